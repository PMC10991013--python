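"""Distribution diagnostics: shape tests, outlier rules, floor/ceiling.

Normality of score distributions is judged with a z-score rule suited to
medium sample sizes: a variable counts as normal when the absolute z-scores
of both sample skewness and excess kurtosis (statistic divided by its
standard error) are below 3.29.  Skewness and kurtosis use the adjusted
Fisher-Pearson estimators (G1 and G2).

Two outlier rules are provided: the adjusted boxplot of Hubert &
Vandervieren, whose fences stretch asymmetrically with the medcouple (a
robust skewness measure), for skewed variables; and the mean +/- k*SD rule
for roughly symmetric scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.stattools import medcouple as sm_medcouple

__all__ = [
    "DistributionDiagnostics",
    "OutlierReport",
    "NORMALITY_Z_THRESHOLD",
    "skew_kurtosis_se",
    "shape_statistics",
    "normality_flag",
    "describe",
    "medcouple",
    "adjusted_boxplot",
    "sd_rule_outliers",
    "floor_ceiling",
]

#: |z| threshold for skewness/kurtosis at medium sample sizes
NORMALITY_Z_THRESHOLD = 3.29


@dataclass(frozen=True)
class DistributionDiagnostics:
    """Descriptive summary of one score distribution.

    MAD is the raw median absolute deviation (no 1.4826 consistency factor),
    as conventional in psychometric descriptive tables.
    """

    mean: float
    sd: float
    median: float
    mad: float
    min: float
    max: float
    se_mean: float
    skewness: float
    kurtosis_excess: float
    z_skew: float
    z_kurt: float
    normal: bool


@dataclass(frozen=True)
class OutlierReport:
    method: str
    fences: tuple[float, float]
    outlier_ids: tuple
    medcouple: float | None = None


def skew_kurtosis_se(n: int) -> tuple[float, float]:
    """Standard errors of sample skewness and excess kurtosis at size n."""
    if n < 4:
        raise ValueError("standard errors require n >= 4")
    se_skew = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    se_kurt = np.sqrt(
        24.0 * n * (n - 1) ** 2 / ((n - 3) * (n - 2) * (n + 3) * (n + 5))
    )
    return float(se_skew), float(se_kurt)


def shape_statistics(x: Sequence[float]) -> tuple[float, float, float, float]:
    """(skewness G1, excess kurtosis G2, z_skew, z_kurt) for a sample."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 4:
        raise ValueError("shape statistics require n >= 4")
    g1 = float(stats.skew(arr, bias=False))
    g2 = float(stats.kurtosis(arr, bias=False))
    se1, se2 = skew_kurtosis_se(arr.size)
    return g1, g2, g1 / se1, g2 / se2


def normality_flag(z_skew: float, z_kurt: float) -> bool:
    """True iff both |z| are strictly below the 3.29 threshold."""
    if not (np.isfinite(z_skew) and np.isfinite(z_kurt)):
        raise ValueError("z scores must be finite")
    return abs(z_skew) < NORMALITY_Z_THRESHOLD and abs(z_kurt) < NORMALITY_Z_THRESHOLD


def describe(x: Sequence[float]) -> DistributionDiagnostics:
    """Full descriptive row: location, spread, range, SE, shape and z flags."""
    arr = np.asarray(x, dtype=float)
    g1, g2, z1, z2 = shape_statistics(arr)
    med = float(np.median(arr))
    return DistributionDiagnostics(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=med,
        mad=float(np.median(np.abs(arr - med))),
        min=float(arr.min()),
        max=float(arr.max()),
        se_mean=float(arr.std(ddof=1) / np.sqrt(arr.size)),
        skewness=g1,
        kurtosis_excess=g2,
        z_skew=z1,
        z_kurt=z2,
        normal=normality_flag(z1, z2),
    )


def medcouple(x: Sequence[float]) -> float:
    """Medcouple MC, a robust measure of skewness in [-1, 1].

    MC is the median of the kernel
    ``h(x_i, x_j) = ((x_j - m) - (m - x_i)) / (x_j - x_i)`` over all pairs
    with ``x_i <= m <= x_j`` and ``x_i != x_j``, where m is the sample
    median.  Pairs of observations both equal to m use the signed special
    kernel: for the q median ties indexed i, j = 1..q,
    h = sign(i + j - 1 - q).  Direct O(n^2) evaluation.
    """
    arr = np.sort(np.asarray(x, dtype=float))
    if arr.size < 3:
        raise ValueError("medcouple requires n >= 3")
    if arr[0] == arr[-1]:
        return float("nan")
    return float(sm_medcouple(arr))


def _quartiles(arr: np.ndarray) -> tuple[float, float]:
    # linear-interpolation quantile convention
    q1, q3 = np.percentile(arr, [25, 75])
    return float(q1), float(q3)


def adjusted_boxplot(
    x: Sequence[float], ids: Sequence | None = None
) -> OutlierReport:
    """Skewness-adjusted boxplot outlier rule (Hubert & Vandervieren).

    With MC >= 0 the fences are
    ``[Q1 - 1.5 exp(-4 MC) IQR,  Q3 + 1.5 exp(3 MC) IQR]``;
    with MC < 0 the exponents swap to (-3 MC, 4 MC).  MC = 0 reduces to the
    classical 1.5*IQR rule.  Values strictly outside the fences are flagged.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 4:
        raise ValueError("adjusted boxplot requires n >= 4")
    labels = np.asarray(ids if ids is not None else np.arange(arr.size))
    mc = medcouple(arr)
    q1, q3 = _quartiles(arr)
    iqr = q3 - q1
    if iqr == 0:
        return OutlierReport("adjusted_boxplot", (q1, q3), (), mc)
    if np.isnan(mc):
        mc = 0.0
    if mc >= 0:
        lo = q1 - 1.5 * np.exp(-4.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(3.0 * mc) * iqr
    else:
        lo = q1 - 1.5 * np.exp(-3.0 * mc) * iqr
        hi = q3 + 1.5 * np.exp(4.0 * mc) * iqr
    mask = (arr < lo) | (arr > hi)
    return OutlierReport(
        "adjusted_boxplot", (float(lo), float(hi)), tuple(labels[mask]), float(mc)
    )


def sd_rule_outliers(
    x: Sequence[float], k: float = 2.5, ids: Sequence | None = None
) -> OutlierReport:
    """Flag values outside mean +/- k standard deviations (default k = 2.5)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("sd rule requires n >= 2")
    labels = np.asarray(ids if ids is not None else np.arange(arr.size))
    mean, sd = arr.mean(), arr.std(ddof=1)
    lo, hi = mean - k * sd, mean + k * sd
    mask = (arr < lo) | (arr > hi)
    return OutlierReport("sd_rule", (float(lo), float(hi)), tuple(labels[mask]))


def floor_ceiling(
    x: Sequence[float], min_possible: float, max_possible: float
) -> dict[str, float]:
    """Counts and proportions of scores at the theoretical bounds."""
    arr = np.asarray(x, dtype=float)
    if ((arr < min_possible) | (arr > max_possible)).any():
        raise ValueError("observed values outside the theoretical bounds")
    n = arr.size
    floor = int((arr == min_possible).sum())
    ceiling = int((arr == max_possible).sum())
    return {
        "floor_count": floor,
        "ceiling_count": ceiling,
        "floor_proportion": floor / n,
        "ceiling_proportion": ceiling / n,
    }
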