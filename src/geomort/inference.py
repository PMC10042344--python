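"""Posterior sampling and coefficient summaries.

The sampler is a blocked adaptive random-walk Metropolis scheme:

* (alpha, beta) jointly, with a proposal covariance adapted to the
  running posterior covariance during burn-in;
* the spatial field by vectorized single-site Metropolis over the two
  checkerboard colours of the rook lattice (same-colour cells are
  conditionally independent given the other colour), with the field
  mean transferred into the intercepts after every sweep so the
  sum-to-zero constraint holds exactly;
* log sigma_zeta by scalar random walk.

Step sizes adapt only during burn-in, so the retained chain is Markov.
Chains are seeded deterministically from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ClusterData,
    LatentState,
    ModelSpec,
    build_precision,
)
from .preprocessing import DesignMatrix

__all__ = ["MCMCConfig", "PosteriorSamples", "CoefficientSummary", "fit",
           "summarize"]

RHAT_LIMIT = 1.05


@dataclass
class MCMCConfig:
    chains: int = 2
    iterations: int = 4000
    burnin: int | None = None      # default: half of iterations
    thin: int | None = None        # default: keep <= 1000 draws per chain
    seed: int = 0
    target_accept_block: float = 0.28
    target_accept_site: float = 0.44

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.burnin is None:
            self.burnin = self.iterations // 2
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burnin must lie inside the iteration budget")
        if self.thin is None:
            kept = self.iterations - self.burnin
            self.thin = max(1, kept // 1000)


@dataclass
class PosteriorSamples:
    """Post-burn-in draws, kept per chain, plus the pointwise log-lik."""

    alpha: np.ndarray              # (chains, draws, n_surveys)
    beta: np.ndarray               # (chains, draws, n_covariates)
    zeta: np.ndarray | None        # (chains, draws, ncells) or None
    sigma: np.ndarray | None       # (chains, draws) or None
    loglik: np.ndarray             # (chains*draws, n_obs)
    covariates: list[str]
    survey_years: list
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    @property
    def alpha_flat(self) -> np.ndarray:
        return self._flat(self.alpha)

    @property
    def beta_flat(self) -> np.ndarray:
        return self._flat(self.beta)

    @property
    def zeta_flat(self) -> np.ndarray | None:
        return None if self.zeta is None else self._flat(self.zeta)

    @property
    def sigma_flat(self) -> np.ndarray | None:
        return None if self.sigma is None else self.sigma.reshape(-1)

    def parameter_names(self) -> list[str]:
        names = [f"alpha_{y}" for y in self.survey_years]
        names += [f"beta_{c}" for c in self.covariates]
        if self.sigma is not None:
            names.append("sigma_zeta")
        return names

    def parameter_matrix(self) -> np.ndarray:
        cols = [self.alpha_flat]
        if self.beta_flat.shape[1]:
            cols.append(self.beta_flat)
        if self.sigma is not None:
            cols.append(self.sigma_flat[:, None])
        return np.hstack(cols)


def _neighbor_sums(z: np.ndarray) -> np.ndarray:
    s = np.zeros_like(z)
    s[:-1, :] += z[1:, :]
    s[1:, :] += z[:-1, :]
    s[:, :-1] += z[:, 1:]
    s[:, 1:] += z[:, :-1]
    return s


def _degrees(nr: int, nc: int) -> np.ndarray:
    """Rook-neighbour count per cell (handles degenerate 1-wide grids)."""
    d = np.zeros((nr, nc))
    d[:-1, :] += 1; d[1:, :] += 1
    d[:, :-1] += 1; d[:, 1:] += 1
    return d


def _low_frequency_modes(nr: int, nc: int, data: ClusterData, n_surveys: int,
                         n_modes: int = 64):
    """Lowest non-constant Laplacian eigenmodes of the lattice.

    Returns the orthonormal mode matrix B (ncells, M), their eigenvalues,
    and the per-survey mean of each mode over that survey's observation
    cells (used to keep mode moves likelihood-neutral on average).
    """
    import scipy.fft

    from .model import icar_grid_eigenvalues

    lam = icar_grid_eigenvalues(nr, nc)
    order = np.argsort(lam.ravel())[1: n_modes + 1]  # skip the constant mode
    cols, vals = [], []
    for flat in order:
        kr, kc = divmod(int(flat), nc)
        coef = np.zeros((nr, nc))
        coef[kr, kc] = 1.0
        cols.append(scipy.fft.idctn(coef, type=2, norm="ortho").ravel())
        vals.append(lam[kr, kc])
    B = np.column_stack(cols)
    mB = np.zeros((n_surveys, B.shape[1]))
    for t in range(n_surveys):
        sel = data.survey == t
        if sel.any():
            mB[t] = B[data.cell[sel]].mean(axis=0)
    return B, np.asarray(vals), mB


def _fast_loglik(y, n, eta):
    """Binomial log-likelihood kernel without the combinatorial constant.

    The constant cancels in every Metropolis ratio on fixed data, so the
    chain uses y*eta - n*log(1 + e^eta); the reported pointwise matrix L
    is computed afterwards with the full log-pmf.
    """
    return y * eta - n * np.logaddexp(0.0, eta)


def _aggregate(data: ClusterData, X: np.ndarray):
    """Pool observations with identical (cell, survey, covariates).

    Binomials with a common success probability add, so the chain's
    likelihood can be evaluated on the pooled counts.
    """
    key = np.column_stack([data.cell.astype(float),
                           data.survey.astype(float), X])
    _, first, inv = np.unique(key, axis=0, return_index=True,
                              return_inverse=True)
    y = np.bincount(inv, weights=data.y)
    n = np.bincount(inv, weights=data.n)
    agg = ClusterData(y=y, n=n, cell=data.cell[first],
                      survey=data.survey[first])
    return agg, X[first]


def _map_alpha_beta(data: ClusterData, X: np.ndarray, T: int, Z: int,
                    alpha_sd: float, beta_sd: float):
    """Penalized-likelihood mode of (alpha, beta) with zeta = 0.

    Newton iterations with step halving on the binomial GLM; returns the
    mode and the negative Hessian there (the Fisher information plus the
    prior precision), used to initialize and pre-scale the block sampler.
    """
    nobs = data.nobs
    A = np.zeros((nobs, T + Z))
    A[np.arange(nobs), data.survey] = 1.0
    if Z:
        A[:, T:] = X
    prior_prec = np.diag([1.0 / alpha_sd**2] * T + [1.0 / beta_sd**2] * Z)
    p0 = np.clip(data.y.sum() / data.n.sum(), 1e-3, 1 - 1e-3)
    theta = np.zeros(T + Z)
    theta[:T] = np.log(p0 / (1 - p0))

    def objective(t):
        eta = A @ t
        return float(np.sum(_fast_loglik(data.y, data.n, eta))
                     - 0.5 * t @ prior_prec @ t)

    obj = objective(theta)
    H = prior_prec.copy()
    for _ in range(50):
        eta = A @ theta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = data.n * p * (1.0 - p)
        g = A.T @ (data.y - data.n * p) - prior_prec @ theta
        H = (A * w[:, None]).T @ A + prior_prec
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(20):  # backtrack if the step overshoots
            cand = theta + scale * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            return theta, H
        moved = float(np.max(np.abs(scale * step)))
        theta, obj = cand, cand_obj
        if moved < 1e-9:
            break
    return theta, H


def _run_chain(chain_seed: np.random.SeedSequence, spec: ModelSpec,
               data: ClusterData, X: np.ndarray, cfg: MCMCConfig,
               cell_X: np.ndarray | None = None):
    rng = np.random.default_rng(chain_seed)
    data, X = _aggregate(data, X)
    T, Z = spec.n_surveys, X.shape[1]
    d_block = T + Z
    nr, nc = spec.geometry.nrows, spec.geometry.ncols
    K = nr * nc
    spatial = spec.spatial

    # --- init: overdispersed around the GLM mode, Fisher-scaled ---
    theta_map, H = _map_alpha_beta(data, X, T, Z, spec.alpha_prior_sd,
                                   spec.beta_prior_sd)
    H_chol = np.linalg.cholesky(H + 1e-9 * np.eye(d_block))
    # draws from N(theta_map, 4 H^-1): distinct starts inside the
    # posterior's scale so convergence diagnostics stay meaningful
    theta0 = theta_map + 2.0 * np.linalg.solve(
        H_chol.T, rng.standard_normal(d_block))
    alpha = theta0[:T].copy()
    beta = theta0[T:].copy()
    zeta = np.zeros((nr, nc))
    sigma = float(np.exp(rng.normal(-0.7, 0.4))) if spatial else 1.0

    if spatial:
        deg = _degrees(nr, nc)
        colors = ((np.add.outer(np.arange(nr), np.arange(nc))) % 2).astype(bool)
        Q0 = build_precision(spec.geometry)
        cell_r, cell_c = np.divmod(data.cell, nc)
        # Confounding-swap geometry: smooth covariates and the field span
        # overlapping likelihood directions; moves beta_z -> beta_z + d,
        # zeta -> zeta - d * (X_z on the grid, centred), alpha -> alpha -
        # d * mean(X_z) leave the likelihood invariant and are accepted on
        # the prior ratio alone, decorrelating beta from the field.
        swap = spatial and cell_X is not None and Z > 0
        if swap:
            grid_means = cell_X.mean(axis=0)
            Xg = cell_X - grid_means            # (K, Z), column-centred
            QXg = np.asarray(Q0 @ Xg)           # (K, Z)
            xqx = np.einsum("kz,kz->z", Xg, QXg)
            log_step_swap = np.full(Z, np.log(0.5))
            acc_swap = np.zeros(Z)
            n_swap = 0
        # Large-scale field modes mix slowly under single-site updates and
        # are confounded with the survey intercepts.  Dedicated moves walk
        # along the lowest Laplacian eigenmodes (orthonormal DCT basis) with
        # a compensating shift of each survey's intercept.
        B, lamB, mB = _low_frequency_modes(nr, nc, data, T)
        M = B.shape[1]
        log_step_mode = np.full(M, np.log(0.5))
        acc_mode = np.zeros(M)
        n_mode = 0
        log_step_scale = np.log(0.1)

    def eta_fixed_of(a, b):
        e = a[data.survey]
        if Z:
            e = e + X @ b
        return e

    eta_fixed = eta_fixed_of(alpha, beta)
    ll_obs = _fast_loglik(data.y, data.n, eta_fixed + zeta[cell_r, cell_c]
                             if spatial else eta_fixed)
    ll_sum = float(ll_obs.sum())

    def block_logprior(a, b):
        lp = -0.5 * np.sum(a**2) / spec.alpha_prior_sd**2
        if Z:
            lp += -0.5 * np.sum(b**2) / spec.beta_prior_sd**2
        return lp

    lp_block = block_logprior(alpha, beta)

    # --- adaptation state ---
    log_s_block = np.log(2.38 / np.sqrt(d_block))
    welford_n = 0
    welford_mean = np.zeros(d_block)
    welford_m2 = np.eye(d_block) * 1e-4
    chol = np.linalg.solve(H_chol.T, np.eye(d_block))  # chol of H^-1
    log_step_color = [np.log(0.5), np.log(0.5)]
    log_step_sigma = np.log(0.5)
    acc_block = acc_sigma = 0
    n_block = n_sigma = 0
    acc_site = 0.0
    n_site = 0

    kept_alpha, kept_beta, kept_zeta, kept_sigma = [], [], [], []

    for it in range(cfg.iterations):
        adapting = it < cfg.burnin
        gamma = (it + 1) ** -0.6

        # ---- (alpha, beta) block ----
        eps = rng.standard_normal(d_block)
        step = np.exp(log_s_block) * (chol @ eps)
        a_new = alpha + step[:T]
        b_new = beta + step[T:]
        eta_new = eta_fixed_of(a_new, b_new)
        eta_tot = eta_new + (zeta[cell_r, cell_c] if spatial else 0.0)
        ll_new_obs = _fast_loglik(data.y, data.n, eta_tot)
        ll_new = float(ll_new_obs.sum())
        lp_new = block_logprior(a_new, b_new)
        log_acc = (ll_new + lp_new) - (ll_sum + lp_block)
        accepted = np.log(rng.uniform()) < log_acc
        if accepted:
            alpha, beta = a_new, b_new
            eta_fixed = eta_new
            ll_obs = ll_new_obs
            ll_sum = ll_new
            lp_block = lp_new
        n_block += 1
        acc_block += accepted
        if adapting:
            log_s_block += gamma * ((1.0 if accepted else 0.0)
                                    - cfg.target_accept_block)
            theta = np.concatenate([alpha, beta])
            welford_n += 1
            delta = theta - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += np.outer(delta, theta - welford_mean)
            if welford_n > 2 * d_block and it % 25 == 0:
                cov = welford_m2 / (welford_n - 1) + 1e-9 * np.eye(d_block)
                chol = np.linalg.cholesky(cov)

        if spatial:
            # ---- checkerboard field updates ----
            inv2s2 = 1.0 / (2.0 * sigma**2)
            for color in (0, 1):
                cmask = colors == bool(color)
                prop = zeta + np.exp(log_step_color[color]) * \
                    rng.standard_normal((nr, nc)) * cmask
                ll_prop_obs = _fast_loglik(
                    data.y, data.n, eta_fixed + prop[cell_r, cell_c])
                dll_cell = np.zeros(K)
                np.add.at(dll_cell, data.cell, ll_prop_obs - ll_obs)
                dll = dll_cell.reshape(nr, nc)
                s_nb = _neighbor_sums(zeta)
                dz = prop - zeta
                dprior = -inv2s2 * (deg * (prop**2 - zeta**2)
                                    - 2.0 * dz * s_nb)
                log_u = np.log(rng.uniform(size=(nr, nc)))
                accept = cmask & (log_u < dll + dprior)
                if accept.any():
                    zeta = np.where(accept, prop, zeta)
                    obs_acc = accept[cell_r, cell_c]
                    ll_obs = np.where(obs_acc, ll_prop_obs, ll_obs)
                    ll_sum = float(ll_obs.sum())
                frac = accept.sum() / cmask.sum()
                if adapting:
                    log_step_color[color] += gamma * \
                        (frac - cfg.target_accept_site)
                acc_site += frac
                n_site += 1

            # ---- recenter: move the field mean into the intercepts ----
            m = zeta.mean()
            if m != 0.0:
                zeta = zeta - m
                alpha = alpha + m
                eta_fixed = eta_fixed + m
                lp_block = block_logprior(alpha, beta)

            quad = float(zeta.ravel() @ (Q0 @ zeta.ravel()))

            if swap:
                # ---- likelihood-invariant beta/field swaps ----
                inv2s2 = 1.0 / (2.0 * sigma**2)
                for z in range(Z):
                    d = np.exp(log_step_swap[z]) * rng.standard_normal()
                    zf = zeta.ravel()
                    cross = float(QXg[:, z] @ zf)
                    quad_new = quad - 2.0 * d * cross + d * d * xqx[z]
                    b_new = beta[z] + d
                    a_new = alpha - d * grid_means[z]
                    dlp = (
                        -inv2s2 * (quad_new - quad)
                        - 0.5 * (b_new**2 - beta[z]**2) / spec.beta_prior_sd**2
                        - 0.5 * (np.sum(a_new**2) - np.sum(alpha**2))
                        / spec.alpha_prior_sd**2)
                    acc = np.log(rng.uniform()) < dlp
                    if acc:
                        zeta = (zf - d * Xg[:, z]).reshape(nr, nc)
                        beta = beta.copy()
                        beta[z] = b_new
                        alpha = a_new
                        quad = quad_new
                        eta_fixed = eta_fixed + d * (X[:, z] - grid_means[z])
                        lp_block = block_logprior(alpha, beta)
                    acc_swap[z] += acc
                    if adapting:
                        log_step_swap[z] += gamma * \
                            ((1.0 if acc else 0.0) - cfg.target_accept_site)
                n_swap += 1

            # ---- low-frequency mode moves with intercept compensation ----
            inv2s2 = 1.0 / (2.0 * sigma**2)
            for m_idx in range(M):
                c = np.exp(log_step_mode[m_idx]) * rng.standard_normal()
                zf = zeta.ravel()
                proj = float(B[:, m_idx] @ zf)
                quad_new = quad + 2.0 * c * lamB[m_idx] * proj \
                    + c * c * lamB[m_idx]
                a_new = alpha - c * mB[:, m_idx]
                deta = c * (B[data.cell, m_idx] - mB[data.survey, m_idx])
                ll_new_obs = _fast_loglik(
                    data.y, data.n,
                    eta_fixed + zf[data.cell] + deta)
                dlp = (
                    float(ll_new_obs.sum()) - ll_sum
                    - inv2s2 * (quad_new - quad)
                    - 0.5 * (np.sum(a_new**2) - np.sum(alpha**2))
                    / spec.alpha_prior_sd**2)
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    zeta = (zf + c * B[:, m_idx]).reshape(nr, nc)
                    alpha = a_new
                    quad = quad_new
                    eta_fixed = eta_fixed - c * mB[data.survey, m_idx]
                    ll_obs = ll_new_obs
                    ll_sum = float(ll_obs.sum())
                    lp_block = block_logprior(alpha, beta)
                acc_mode[m_idx] += acc
                if adapting:
                    log_step_mode[m_idx] += gamma * \
                        ((1.0 if acc else 0.0) - cfg.target_accept_site)
            n_mode += 1

            # ---- joint rescaling of the field and its SD ----
            r = float(np.exp(np.exp(log_step_scale) * rng.standard_normal()))
            zf = zeta.ravel()
            ll_new_obs = _fast_loglik(
                data.y, data.n, eta_fixed + r * zf[data.cell])
            s_new = r * sigma
            # GMRF density is invariant under (zeta, sigma) -> (r zeta,
            # r sigma) except for the -(K-1) log sigma term; with the
            # K-dim log-Jacobian the net structural term is +log r.
            dlp = (
                float(ll_new_obs.sum()) - ll_sum
                + np.log(r)
                - 0.5 * (s_new**2 - sigma**2) / spec.sigma_prior_sd**2)
            acc = np.log(rng.uniform()) < dlp
            if acc:
                zeta = (r * zf).reshape(nr, nc)
                sigma = s_new
                quad = r * r * quad
                ll_obs = ll_new_obs
                ll_sum = float(ll_obs.sum())
            if adapting:
                log_step_scale += gamma * ((1.0 if acc else 0.0)
                                           - cfg.target_accept_site)

            # ---- sigma on log scale ----

            def sigma_logpost(s):
                return (-(K - 1) * np.log(s) - quad / (2.0 * s**2)
                        - 0.5 * s**2 / spec.sigma_prior_sd**2 + np.log(s))

            s_new = sigma * np.exp(np.exp(log_step_sigma)
                                   * rng.standard_normal())
            log_acc = sigma_logpost(s_new) - sigma_logpost(sigma)
            acc = np.log(rng.uniform()) < log_acc
            if acc:
                sigma = s_new
            n_sigma += 1
            acc_sigma += acc
            if adapting:
                log_step_sigma += gamma * ((1.0 if acc else 0.0)
                                           - cfg.target_accept_site)

        if not adapting and (it - cfg.burnin) % cfg.thin == 0:
            kept_alpha.append(alpha.copy())
            kept_beta.append(beta.copy())
            if spatial:
                kept_zeta.append(zeta.ravel().copy())
                kept_sigma.append(sigma)

    out = {
        "alpha": np.array(kept_alpha),
        "beta": np.array(kept_beta).reshape(len(kept_alpha), Z),
        "zeta": np.array(kept_zeta) if spatial else None,
        "sigma": np.array(kept_sigma) if spatial else None,
        "accept_block": acc_block / max(n_block, 1),
        "accept_site": acc_site / max(n_site, 1) if spatial else None,
        "accept_sigma": acc_sigma / max(n_sigma, 1) if spatial else None,
        "accept_swap": (acc_swap / max(n_swap, 1)).tolist()
        if spatial and cell_X is not None and Z > 0 else None,
    }
    return out


def fit(spec: ModelSpec, data: ClusterData, design: DesignMatrix,
        mcmc: MCMCConfig | None = None,
        survey_years: list | None = None,
        cell_covariates: np.ndarray | None = None) -> PosteriorSamples:
    """Sample the posterior of the binomial spatial regression.

    ``cell_covariates`` (ncells, n_covariates), the standardized covariate
    surfaces on the model grid, enables likelihood-invariant swap moves
    between the coefficients and the spatial field; strongly recommended
    for spatial fits (the pipeline passes it automatically).
    """
    from .validation import pointwise_loglik

    mcmc = mcmc or MCMCConfig()
    X = np.asarray(design.X, dtype=float)
    if X.shape[0] != data.nobs:
        raise ValueError("design matrix and cluster data are misaligned")
    if X.shape[1] and np.any(X.std(axis=0) == 0):
        bad = [n for n, s in zip(design.names, X.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance design columns: {bad}")
    if data.survey.max() >= spec.n_surveys:
        raise ValueError("survey index exceeds spec.n_surveys")

    # probe the initial posterior for finiteness
    probe = LatentState(
        alpha=np.zeros(spec.n_surveys), beta=np.zeros(X.shape[1]),
        zeta=np.zeros(spec.ncells if spec.spatial else 0), sigma=1.0)
    from .model import log_likelihood

    if not np.isfinite(log_likelihood(probe, data, X)):
        raise ValueError("non-finite initial posterior")

    if cell_covariates is not None:
        cell_covariates = np.asarray(cell_covariates, dtype=float)
        if cell_covariates.shape != (spec.ncells, X.shape[1]):
            raise ValueError("cell_covariates must be (ncells, n_covariates)")
        # swap moves are likelihood-invariant only when the cluster design
        # equals the grid surface at the cluster cells
        if not np.allclose(cell_covariates[data.cell], X,
                           atol=1e-8, equal_nan=False):
            warnings.warn(
                "cell_covariates disagree with the design matrix at the "
                "cluster cells; disabling field/coefficient swap moves",
                RuntimeWarning, stacklevel=2)
            cell_covariates = None
        else:
            # NODATA cells never touch the likelihood; a zero direction
            # there keeps the moves valid
            cell_covariates = np.nan_to_num(cell_covariates, nan=0.0)

    seeds = [np.random.SeedSequence([int(mcmc.seed), 7919, c])
             for c in range(mcmc.chains)]
    chains = [_run_chain(s, spec, data, X, mcmc, cell_covariates)
              for s in seeds]

    alpha = np.stack([c["alpha"] for c in chains])
    beta = np.stack([c["beta"] for c in chains])
    spatial = spec.spatial
    zeta = np.stack([c["zeta"] for c in chains]) if spatial else None
    sigma = np.stack([c["sigma"] for c in chains]) if spatial else None

    samples = PosteriorSamples(
        alpha=alpha, beta=beta, zeta=zeta, sigma=sigma,
        loglik=np.zeros((0, 0)),
        covariates=list(design.names),
        survey_years=list(survey_years) if survey_years is not None
        else list(range(spec.n_surveys)),
        metadata={
            "seed": mcmc.seed,
            "chains": mcmc.chains,
            "iterations": mcmc.iterations,
            "burnin": mcmc.burnin,
            "thin": mcmc.thin,
            "accept_block": [c["accept_block"] for c in chains],
            "accept_site": [c["accept_site"] for c in chains],
            "accept_sigma": [c["accept_sigma"] for c in chains],
            "accept_swap": [c["accept_swap"] for c in chains],
        },
    )
    samples.loglik = pointwise_loglik(samples, data, X)
    samples.metadata["rhat"] = _split_rhat(samples)
    bad = {k: v for k, v in samples.metadata["rhat"].items()
           if np.isfinite(v) and v > RHAT_LIMIT}
    samples.metadata["converged"] = not bad
    if bad:
        warnings.warn(
            f"split R-hat above {RHAT_LIMIT} for: "
            + ", ".join(f"{k}={v:.3f}" for k, v in bad.items()),
            RuntimeWarning, stacklevel=2)
    return samples


def _split_rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Split R-hat per scalar parameter (arviz)."""
    import arviz as az

    out: dict[str, float] = {}
    names = samples.parameter_names()
    C, S = samples.alpha.shape[:2]
    if C * S < 4:
        return {n: float("nan") for n in names}
    mats = [samples.alpha[:, :, i] for i in range(samples.alpha.shape[2])]
    mats += [samples.beta[:, :, i] for i in range(samples.beta.shape[2])]
    if samples.sigma is not None:
        mats.append(samples.sigma)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, m in zip(names, mats):
            out[name] = float(az.rhat(az.convert_to_dataset(m[None] if m.ndim == 1
                                                            else m))["x"].values)
    return out


@dataclass
class CoefficientSummary:
    name: str
    mean: float
    lower: float
    upper: float
    significant: bool


def summarize(samples: PosteriorSamples, level: float = 0.95):
    """Posterior mean and equal-tailed credible interval per coefficient.

    An effect is flagged significant when zero lies outside its interval,
    the usual Bayesian reporting rule for regression tables.
    Returns a DataFrame indexed by parameter name.
    """
    import pandas as pd

    if samples.n_draws == 0:
        raise ValueError("empty posterior samples")
    if samples.n_draws < 100:
        warnings.warn("fewer than 100 draws: quantiles may be unstable",
                      RuntimeWarning, stacklevel=2)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    mat = samples.parameter_matrix()
    names = samples.parameter_names()
    rows = []
    for j, name in enumerate(names):
        col = mat[:, j]
        lo, hi = np.quantile(col, [lo_q, hi_q])
        sig = bool(not (lo <= 0.0 <= hi)) and not name.startswith("sigma")
        rows.append((name, float(col.mean()), float(lo), float(hi), sig))
    df = pd.DataFrame(rows, columns=["parameter", "mean", "lower", "upper",
                                     "significant"]).set_index("parameter")
    return df
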