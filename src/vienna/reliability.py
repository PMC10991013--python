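"""Polychoric correlations and ordinal alpha for the VIENNA item scores.

Internal consistency of ordinal 0/1/2 item scores is assessed on the latent
scale: each item is treated as a discretization of a standard-normal latent
variable at item-specific thresholds, the polychoric correlation of each item
pair is estimated, and Cronbach's alpha is computed from the resulting
correlation matrix ("polychoric ordinal alpha").

Estimation is the classical two-step procedure: thresholds are fixed at the
inverse-normal of the observed cumulative margins, then the latent correlation
rho maximizes the multinomial log-likelihood of the contingency table with
cell probabilities given by bivariate-normal rectangle integrals.  The
rectangle integrals use an Owen's-T evaluation of the bivariate normal CDF,
which is exact and fast enough for bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "PolychoricResult",
    "AlphaResult",
    "bvn_cdf",
    "latent_thresholds",
    "polychoric_corr",
    "ordinal_alpha",
    "polychoric_matrix",
    "alpha_pipeline",
]

logger = logging.getLogger(__name__)

#: |rho| is bounded away from +-1 so the likelihood stays finite
RHO_BOUND = 0.999


def bvn_cdf(h, k, rho: float):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Vectorized over ``h`` and ``k`` (broadcast); ``rho`` is scalar.  Uses the
    Owen's-T decomposition, with explicit handling of infinite bounds, zero
    bounds, and |rho| = 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if abs(rho) >= 1.0:
        if rho >= 1.0:
            return stats.norm.cdf(np.minimum(h, k))
        return np.clip(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0, None)

    out = np.full(h.shape, np.nan)
    neg_inf = np.isneginf(h) | np.isneginf(k)
    out[neg_inf] = 0.0
    h_inf = np.isposinf(h) & ~neg_inf
    out[h_inf] = stats.norm.cdf(k[h_inf])
    k_inf = np.isposinf(k) & ~h_inf & ~neg_inf
    out[k_inf] = stats.norm.cdf(h[k_inf])

    fin = ~(neg_inf | h_inf | k_inf)
    hf, kf = h[fin], k[fin]
    d = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_h = np.where(hf != 0, (kf - rho * hf) / (hf * d), np.nan)
        a_k = np.where(kf != 0, (hf - rho * kf) / (kf * d), np.nan)
    # T-term limits as a bound approaches 0 from above: T -> sign(other)/4
    t_h = np.where(hf != 0, special.owens_t(hf, np.nan_to_num(a_h)), 0.25 * np.sign(kf))
    t_k = np.where(kf != 0, special.owens_t(kf, np.nan_to_num(a_k)), 0.25 * np.sign(hf))
    beta = np.where((hf * kf > 0) | ((hf * kf == 0) & (hf + kf >= 0)), 0.0, 0.5)
    val = 0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf)) - t_h - t_k - beta
    both_zero = (hf == 0) & (kf == 0)
    val[both_zero] = 0.25 + np.arcsin(rho) / (2.0 * np.pi)
    out[fin] = np.clip(val, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    thresholds_x: tuple[float, ...]
    thresholds_y: tuple[float, ...]
    loglik: float
    converged: bool


@dataclass(frozen=True)
class AlphaResult:
    """Ordinal alpha with bootstrap CI and the item-exclusion audit trail."""

    alpha: float
    ci_low: float
    ci_high: float
    k_items: int
    excluded_items: dict[str, str] = field(default_factory=dict)


def latent_thresholds(freqs) -> np.ndarray:
    """Latent standard-normal cut-points from observed category frequencies.

    Cut-point j is the inverse normal CDF of the cumulative proportion
    through category j (the first step of two-step polychoric estimation).
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.size < 2:
        raise ValueError("need at least two categories")
    n = f.sum()
    if (f == n).any():
        raise ValueError("one category holds all observations (zero variance)")
    if (f > 0).sum() < 2:
        raise ValueError("need at least two nonempty categories")
    cum = np.cumsum(f)[:-1] / n
    return special.ndtri(cum)


def _rectangle_probs(thr_x: np.ndarray, thr_y: np.ndarray, rho: float) -> np.ndarray:
    gx = np.concatenate(([-np.inf], thr_x, [np.inf]))
    gy = np.concatenate(([-np.inf], thr_y, [np.inf]))
    grid = bvn_cdf(gx[:, None], gy[None, :], rho)
    return grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]


def polychoric_corr(table) -> PolychoricResult:
    """Two-step polychoric correlation from a contingency table.

    Rows index categories of one ordinal variable, columns the other.
    Categories with zero margin are dropped.  rho is found by bounded 1-D
    maximization of the multinomial log-likelihood over [-0.999, 0.999].
    """
    obs = np.asarray(table, dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 nonempty rows and columns")
    thr_x = latent_thresholds(obs.sum(axis=1))
    thr_y = latent_thresholds(obs.sum(axis=0))

    tiny = 1e-300

    def negloglik(rho: float) -> float:
        p = np.clip(_rectangle_probs(thr_x, thr_y, rho), tiny, None)
        return -float((obs * np.log(p)).sum())

    res = optimize.minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    return PolychoricResult(
        rho=float(res.x),
        thresholds_x=tuple(thr_x),
        thresholds_y=tuple(thr_y),
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


def ordinal_alpha(corr) -> float:
    """Cronbach-type alpha from a correlation matrix.

    alpha = (k/(k-1)) * (1 - k/S) with S the sum of all matrix entries;
    equivalent to k*rbar / (1 + (k-1)*rbar) for average off-diagonal rbar.
    Returns NaN when S <= 0.
    """
    r = np.asarray(corr, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] < 2:
        raise ValueError("need a square correlation matrix with k >= 2")
    if not np.allclose(r, r.T, atol=1e-8) or not np.allclose(np.diag(r), 1.0):
        raise ValueError("matrix must be symmetric with unit diagonal")
    k = r.shape[0]
    s = float(r.sum())
    if s <= 0:
        return float("nan")
    return (k / (k - 1)) * (1.0 - k / s)


def _nearest_psd(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping repair for an indefinite pairwise matrix."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= -tol:
        return r
    logger.info(
        "pairwise polychoric matrix not positive semi-definite "
        "(min eigenvalue %.2e); clipping", vals.min()
    )
    vals = np.clip(vals, tol, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def polychoric_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise polychoric correlation matrix over an items table."""
    items = list(scores.columns)
    k = len(items)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            tab = pd.crosstab(scores[items[i]], scores[items[j]])
            res = polychoric_corr(tab.to_numpy())
            if not res.converged:
                logger.warning(
                    "polychoric fit did not converge for (%s, %s)",
                    items[i], items[j],
                )
            r[i, j] = r[j, i] = res.rho
    r = _nearest_psd(r)
    return pd.DataFrame(r, index=items, columns=items)


def alpha_pipeline(
    scores: pd.DataFrame,
    variance_threshold: float | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> AlphaResult:
    """Polychoric ordinal alpha with the item-exclusion rules.

    Zero-variance items are always excluded (their thresholds are
    degenerate); with ``variance_threshold`` set, only items whose sample
    variance exceeds the threshold are retained.  The 95% CI is a percentile
    bootstrap over participants (``n_boot`` resamples; 0 disables it).
    """
    excluded: dict[str, str] = {}
    keep = []
    for item in scores.columns:
        var = float(scores[item].var(ddof=1))
        if var == 0.0:
            excluded[str(item)] = "zero variance"
        elif variance_threshold is not None and var <= variance_threshold:
            excluded[str(item)] = f"variance {var:.3f} <= {variance_threshold}"
        else:
            keep.append(item)
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 items remain after exclusions: {excluded}"
        )
    kept = scores[keep]
    alpha = ordinal_alpha(polychoric_matrix(kept).to_numpy())

    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(kept)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = kept.iloc[idx]
            # resampling can empty a score category or zero out an item;
            # such draws are skipped rather than silently re-specified
            try:
                boots.append(ordinal_alpha(polychoric_matrix(sample).to_numpy()))
            except ValueError:
                continue
        boots = np.asarray([b for b in boots if np.isfinite(b)])
        if boots.size:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return AlphaResult(
        alpha=float(alpha),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        k_items=len(keep),
        excluded_items=excluded,
    )
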