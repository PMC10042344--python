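"""Predictive model checks: CPO, PIT and WAIC.

All three are computed from the S-by-n matrix L of per-draw,
per-observation binomial log-likelihoods.

* CPO_i (conditional predictive ordinate) uses the harmonic-mean
  importance identity CPO_i = [ (1/S) sum_s exp(-L[s,i]) ]^-1, evaluated
  in log space; observations whose importance weights have effective
  sample size below 0.1 S are flagged unreliable.
* PIT_i is the mid-PIT, P(Y_rep < y_i) + 0.5 P(Y_rep = y_i), under the
  leave-one-out predictive (the same importance weights as CPO); the
  mid correction restores approximate uniformity for discrete counts.
* WAIC = -2 (lppd - p_waic) with lppd the log pointwise predictive
  density and p_waic the summed posterior variance of L (S-1 in the
  denominator).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom as binom_dist

from .model import ClusterData, binomial_logpmf

__all__ = [
    "ValidationReport",
    "pointwise_loglik",
    "compute_cpo",
    "compute_pit",
    "compute_waic",
    "validate",
    "compare_models",
]


def _eta_draws(samples, data: ClusterData, X: np.ndarray) -> np.ndarray:
    """Per-draw linear predictors for every observation, (S, n)."""
    eta = samples.alpha_flat[:, data.survey]
    if X.shape[1]:
        eta = eta + samples.beta_flat @ X.T
    zeta = samples.zeta_flat
    if zeta is not None:
        eta = eta + zeta[:, data.cell]
    return eta


def pointwise_loglik(samples, data: ClusterData, X: np.ndarray,
                     chunk: int = 256) -> np.ndarray:
    """Matrix L with L[s, i] = binomial log-pmf of observation i at draw s.

    Draws are processed in chunks to bound the memory of the (S, n)
    temporaries on large problems.
    """
    if X.shape[0] != data.nobs:
        raise ValueError("design matrix and data are misaligned")
    S = samples.n_draws
    L = np.empty((S, data.nobs))
    for start in range(0, S, chunk):
        sl = slice(start, min(start + chunk, S))
        eta = samples.alpha_flat[sl][:, data.survey]
        if X.shape[1]:
            eta = eta + samples.beta_flat[sl] @ X.T
        zeta = samples.zeta_flat
        if zeta is not None:
            eta = eta + zeta[sl][:, data.cell]
        L[sl] = binomial_logpmf(data.y[None, :], data.n[None, :], eta)
    return L


def compute_cpo(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic-mean CPO per observation plus reliability flags.

    Returns ``(cpo, reliable)``; ``reliable[i]`` is False when the
    effective sample size of the importance weights w_s = exp(-L[s, i])
    falls below 10% of the number of draws.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1:
        raise ValueError("L must be an (S, n) matrix with S >= 1")
    if not np.all(np.isfinite(L)):
        raise ValueError("non-finite log-likelihood rows")
    S = L.shape[0]
    # log CPO_i = log S - logsumexp_s(-L[s,i])
    log_cpo = np.log(S) - logsumexp(-L, axis=0)
    # ESS of weights w = exp(-L): (sum w)^2 / sum w^2, in log space
    log_sum_w = logsumexp(-L, axis=0)
    log_sum_w2 = logsumexp(-2.0 * L, axis=0)
    ess = np.exp(2.0 * log_sum_w - log_sum_w2)
    return np.exp(log_cpo), ess >= 0.1 * S


def compute_pit(samples, data: ClusterData, X: np.ndarray) -> np.ndarray:
    """Leave-one-out mid-PIT per observation.

    Predictive probabilities are averaged over draws with the CPO
    importance weights w_s propto exp(-L[s, i]), approximating the
    posterior with observation i removed.
    """
    L = pointwise_loglik(samples, data, X)
    eta = _eta_draws(samples, data, X)
    # stable per-draw success probabilities
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    log_w = -L - logsumexp(-L, axis=0, keepdims=True)
    w = np.exp(log_w)
    cdf_below = binom_dist.cdf(data.y[None, :] - 1, data.n[None, :], p)
    pmf_at = binom_dist.pmf(data.y[None, :], data.n[None, :], p)
    return np.sum(w * (cdf_below + 0.5 * pmf_at), axis=0)


def compute_waic(L: np.ndarray) -> tuple[float, float, float]:
    """WAIC, effective parameters p_waic, and lppd from the L matrix."""
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    S = L.shape[0]
    lppd = float(np.sum(logsumexp(L, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(L, axis=0, ddof=1)))
    waic = -2.0 * (lppd - p_waic)
    return waic, p_waic, lppd


@dataclass
class ValidationReport:
    """Per-observation checks and model-level WAIC for one fitted model."""

    model_name: str
    cpo: np.ndarray
    cpo_reliable: np.ndarray
    pit: np.ndarray
    waic: float
    p_waic: float
    lppd: float
    n_parameters: int
    data_checksum: str

    @property
    def n_unreliable_cpo(self) -> int:
        return int((~self.cpo_reliable).sum())


def data_checksum(data: ClusterData) -> str:
    h = hashlib.sha256()
    for arr in (data.y, data.n, data.cell, data.survey):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def validate(samples, data: ClusterData, X: np.ndarray,
             model_name: str = "model") -> ValidationReport:
    """Full validation report for one fitted model."""
    L = pointwise_loglik(samples, data, X)
    cpo, reliable = compute_cpo(L)
    pit = compute_pit(samples, data, X)
    waic, p_waic, lppd = compute_waic(L)
    n_par = samples.alpha.shape[2] + samples.beta.shape[2] \
        + (1 if samples.sigma is not None else 0)
    return ValidationReport(
        model_name=model_name, cpo=cpo, cpo_reliable=reliable, pit=pit,
        waic=waic, p_waic=p_waic, lppd=lppd, n_parameters=n_par,
        data_checksum=data_checksum(data))


def compare_models(reports: list[ValidationReport]):
    """Rank models by WAIC (ascending); near-ties favour fewer parameters.

    All reports must come from the same dataset (checksum-verified).
    Returns a DataFrame ordered best-first with Delta-WAIC.
    """
    import pandas as pd

    if not reports:
        raise ValueError("no reports to compare")
    checks = {r.data_checksum for r in reports}
    if len(checks) > 1:
        raise ValueError("reports computed on different datasets")
    order = sorted(range(len(reports)), key=lambda i: reports[i].waic)
    changed = True
    while changed:  # bubble near-ties (|dWAIC| < 1e-9) toward fewer parameters
        changed = False
        for k in range(len(order) - 1):
            a, b = order[k], order[k + 1]
            if (abs(reports[a].waic - reports[b].waic) < 1e-9
                    and reports[a].n_parameters > reports[b].n_parameters):
                order[k], order[k + 1] = b, a
                changed = True
    best = reports[order[0]].waic
    rows = [
        {
            "model": reports[i].model_name,
            "waic": reports[i].waic,
            "p_waic": reports[i].p_waic,
            "lppd": reports[i].lppd,
            "n_parameters": reports[i].n_parameters,
            "delta_waic": reports[i].waic - best,
        }
        for i in order
    ]
    return pd.DataFrame(rows)
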