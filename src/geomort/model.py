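"""Bayesian binomial spatial regression on a raster lattice.

The model for cluster ``j`` with ``n_j`` live births and ``y_j``
under-five deaths is

    y_j ~ Binomial(n_j, p_j),
    logit(p_j) = alpha_{t(j)} + x_j' beta + zeta_{c(j)},

where ``t(j)`` is the survey of cluster ``j``, ``x_j`` the standardized
covariates extracted at its location, and ``zeta`` a zero-mean Gaussian
Markov random field indexed by lattice cell ``c(j)``.  The field prior is
a first-order intrinsic CAR: precision (1/sigma^2) * Q0 with Q0 the rook
graph Laplacian of the grid, under a sum-to-zero constraint.

Priors: alpha_t, beta_z ~ Normal(0, 10^2); sigma_zeta ~ Half-Normal(1).
All functions here are pure in the parameter state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln

from .rasters import GridGeometry

__all__ = [
    "ModelSpec",
    "LatentState",
    "ClusterData",
    "build_precision",
    "icar_generalized_logdet",
    "gmrf_logpdf",
    "binomial_logpmf",
    "log_likelihood",
    "log_posterior",
]


def binomial_logpmf(y, n, eta):
    """Binomial log-pmf with logit-scale parameter, stable at |eta| ~ 40.

    log p = -log(1 + e^-eta) and log(1-p) = -log(1 + e^eta) are evaluated
    with logaddexp so that extreme linear predictors never overflow or
    collapse to log(0).
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    eta = np.asarray(eta, dtype=float)
    log_p = -np.logaddexp(0.0, -eta)
    log_1mp = -np.logaddexp(0.0, eta)
    return (
        gammaln(n + 1.0)
        - gammaln(y + 1.0)
        - gammaln(n - y + 1.0)
        + y * log_p
        + (n - y) * log_1mp
    )


def build_precision(geometry: GridGeometry | tuple[int, int],
                    mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Structure matrix Q0 of the first-order intrinsic CAR (rook lattice).

    Q0 is the graph Laplacian: Q0[i,i] = number of rook neighbours of cell
    i, Q0[i,k] = -1 for neighbouring cells, 0 otherwise.  The full field
    precision is (1/sigma^2) Q0 together with a sum-to-zero constraint.

    ``mask`` optionally marks valid cells; the lattice restricted to valid
    cells must be connected, otherwise the components are reported.
    """
    if isinstance(geometry, GridGeometry):
        nrows, ncols = geometry.nrows, geometry.ncols
    else:
        nrows, ncols = geometry
    if nrows < 1 or ncols < 1:
        raise ValueError("lattice dimensions must be positive")
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    rows, cols = [], []
    # horizontal and vertical rook edges
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel())
    rows.append(idx[:-1, :].ravel()); cols.append(idx[1:, :].ravel())
    i = np.concatenate(rows)
    k = np.concatenate(cols)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        keep = flat_mask[i] & flat_mask[k]
        i, k = i[keep], k[keep]
    n = nrows * ncols
    data = np.ones(i.size)
    adj = sp.coo_matrix((data, (i, k)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    if mask is not None:
        valid = np.flatnonzero(np.asarray(mask, dtype=bool).ravel())
        adj = adj[valid][:, valid]
        n = valid.size
    ncomp, labels = connected_components(adj, directed=False)
    if ncomp > 1 and n > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"lattice is disconnected: {ncomp} components with sizes "
            f"{sizes.tolist()}"
        )
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sp.diags(deg) - adj).tocsr()


def icar_grid_eigenvalues(nrows: int, ncols: int) -> np.ndarray:
    """Eigenvalues of the rook-lattice Laplacian Q0, shaped (nrows, ncols).

    The grid Laplacian is the Kronecker sum of two path-graph Laplacians,
    whose eigenvectors are the orthonormal DCT-II basis; eigenvalues are
    2 - 2cos(pi k / m) along each axis.
    """
    lr = 2.0 - 2.0 * np.cos(np.pi * np.arange(nrows) / nrows)
    lc = 2.0 - 2.0 * np.cos(np.pi * np.arange(ncols) / ncols)
    return lr[:, None] + lc[None, :]


def icar_generalized_logdet(nrows: int, ncols: int) -> float:
    """Log of the product of the non-zero eigenvalues of Q0."""
    lam = icar_grid_eigenvalues(nrows, ncols).ravel()
    lam = lam[lam > 1e-12]
    return float(np.sum(np.log(lam)))


@dataclass
class ClusterData:
    """Modelled cluster observations, mapped to lattice cells.

    Arrays are aligned: observation j has ``y[j]`` deaths out of ``n[j]``
    births, sits in flat lattice cell ``cell[j]`` and belongs to survey
    ``survey[j]`` (0-based index into the survey list).
    """

    y: np.ndarray
    n: np.ndarray
    cell: np.ndarray
    survey: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.cell = np.asarray(self.cell, dtype=int)
        self.survey = np.asarray(self.survey, dtype=int)
        if not (self.y.shape == self.n.shape == self.cell.shape == self.survey.shape):
            raise ValueError("cluster arrays must be aligned")
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("deaths must satisfy 0 <= y <= n")
        if np.any(self.n < 1):
            raise ValueError("modelled clusters need n >= 1")

    @property
    def nobs(self) -> int:
        return self.y.size


@dataclass
class ModelSpec:
    """Model structure: covariates, lattice, surveys and priors."""

    covariates: list[str]
    geometry: GridGeometry
    n_surveys: int = 1
    spatial: bool = True
    alpha_prior_sd: float = 10.0
    beta_prior_sd: float = 10.0
    sigma_prior_sd: float = 1.0
    _logdet_q0: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.alpha_prior_sd, self.beta_prior_sd, self.sigma_prior_sd) <= 0:
            raise ValueError("prior SDs must be positive")
        if self.n_surveys < 1:
            raise ValueError("need at least one survey")

    @property
    def ncells(self) -> int:
        return self.geometry.ncells

    @property
    def logdet_q0(self) -> float:
        if self._logdet_q0 is None:
            self._logdet_q0 = icar_generalized_logdet(
                self.geometry.nrows, self.geometry.ncols
            )
        return self._logdet_q0


@dataclass
class LatentState:
    """One point in parameter space."""

    alpha: np.ndarray   # (n_surveys,)
    beta: np.ndarray    # (n_covariates,)
    zeta: np.ndarray    # (ncells,) — all zeros when the model is non-spatial
    sigma: float        # marginal-scale SD of the spatial field

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) \
            if np.size(self.beta) else np.zeros(0)
        self.zeta = np.asarray(self.zeta, dtype=float)
        self.sigma = float(self.sigma)
        if not (np.all(np.isfinite(self.alpha)) and np.all(np.isfinite(self.beta))
                and np.all(np.isfinite(self.zeta)) and np.isfinite(self.sigma)):
            raise ValueError("state must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma_zeta must be positive")


def linear_predictor(state: LatentState, data: ClusterData, X: np.ndarray) -> np.ndarray:
    eta = state.alpha[data.survey]
    if X.shape[1]:
        eta = eta + X @ state.beta
    if state.zeta.size:
        eta = eta + state.zeta[data.cell]
    return eta


def log_likelihood(state: LatentState, data: ClusterData, X: np.ndarray) -> float:
    """Binomial log-likelihood of the cluster data under ``state``.

    ``X`` is the (n_obs, n_covariates) design matrix (standardized
    covariate values at the cluster locations).
    """
    if X.shape[0] != data.nobs:
        raise ValueError("design matrix and data are misaligned")
    if X.shape[1] != state.beta.size:
        raise ValueError("beta length does not match design matrix")
    eta = linear_predictor(state, data, X)
    return float(np.sum(binomial_logpmf(data.y, data.n, eta)))


def gmrf_logpdf(zeta: np.ndarray, sigma: float, Q0: sp.spmatrix,
                logdet_q0: float) -> float:
    """Log-density of the sum-to-zero ICAR field at ``zeta``.

    The intrinsic field has rank K-1; under the constraint its proper
    density on the contrast space is
        -(K-1)/2 log(2 pi) + 1/2 logdet+(Q0) - (K-1) log sigma
        - zeta' Q0 zeta / (2 sigma^2).
    """
    k = zeta.size
    quad = float(zeta @ (Q0 @ zeta))
    return (
        -0.5 * (k - 1) * np.log(2.0 * np.pi)
        + 0.5 * logdet_q0
        - (k - 1) * np.log(sigma)
        - quad / (2.0 * sigma**2)
    )


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.atleast_1d(x)
    return float(-0.5 * x.size * np.log(2 * np.pi) - x.size * np.log(sd)
                 - 0.5 * np.sum(x**2) / sd**2)


def _halfnormal_logpdf(x: float, sd: float) -> float:
    return float(0.5 * np.log(2.0 / np.pi) - np.log(sd) - 0.5 * x**2 / sd**2)


def log_posterior(state: LatentState, data: ClusterData | None, X: np.ndarray,
                  spec: ModelSpec, Q0: sp.spmatrix | None = None) -> float:
    """Unnormalized log-posterior: likelihood + priors (+ GMRF density)."""
    lp = _normal_logpdf_sum(state.alpha, spec.alpha_prior_sd)
    if state.beta.size:
        lp += _normal_logpdf_sum(state.beta, spec.beta_prior_sd)
    if spec.spatial:
        if Q0 is None:
            Q0 = build_precision(spec.geometry)
        lp += gmrf_logpdf(state.zeta, state.sigma, Q0, spec.logdet_q0)
        lp += _halfnormal_logpdf(state.sigma, spec.sigma_prior_sd)
    if data is not None and data.nobs:
        lp += log_likelihood(state, data, X)
    return lp
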