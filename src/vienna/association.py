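"""Correlation battery relating navigation scores to covariates.

The battery follows standard neuropsychological validation practice:

* Pearson's r for pairs of normally distributed variables (judged by the
  3.29 z-rule in :mod:`vienna.diagnostics`), Spearman's rho otherwise;
* partial correlations controlling for age or for an average-performance
  composite built from the remaining tests;
* Benjamini-Hochberg adjustment over the configured test family;
* Levene-guarded independent-samples t-tests for binary group factors;
* Clogg's Z for the difference of two regression coefficients.

Missing data are never imputed; every analysis is pairwise-complete and
reports the n it actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diagnostics import DistributionDiagnostics, describe

__all__ = [
    "AssociationResult",
    "choose_coefficient",
    "pairwise_corr",
    "partial_corr",
    "average_performance_composite",
    "bh_adjust",
    "ttest_from_summary",
    "levene_check",
    "clogg_z",
    "association_battery",
]


@dataclass(frozen=True)
class AssociationResult:
    x: str
    y: str
    kind: str  # "pearson" | "spearman" | "partial"
    estimate: float
    n: int
    p: float
    p_adjusted: float = float("nan")
    controls: tuple[str, ...] = field(default_factory=tuple)


def choose_coefficient(
    x_diag: DistributionDiagnostics, y_diag: DistributionDiagnostics
) -> str:
    """Pearson iff both variables pass the 3.29 normality rule, else Spearman."""
    return "pearson" if (x_diag.normal and y_diag.normal) else "spearman"


def _complete(*cols: pd.Series) -> list[np.ndarray]:
    df = pd.concat(cols, axis=1).dropna()
    return [df.iloc[:, i].to_numpy(dtype=float) for i in range(df.shape[1])]


def pairwise_corr(x: pd.Series, y: pd.Series, kind: str = "pearson") -> AssociationResult:
    """Pairwise-complete Pearson or Spearman correlation with its p value."""
    xa, ya = _complete(x, y)
    if kind == "pearson":
        est, p = stats.pearsonr(xa, ya)
    elif kind == "spearman":
        est, p = stats.spearmanr(xa, ya)
    else:
        raise ValueError(f"unknown coefficient kind {kind!r}")
    return AssociationResult(
        str(x.name), str(y.name), kind, float(est), len(xa), float(p)
    )


def partial_corr(
    x: pd.Series, y: pd.Series, controls: pd.DataFrame | pd.Series
) -> AssociationResult:
    """Partial correlation of x and y given one or more control variables.

    Computed as the Pearson correlation of the residuals of x and y after
    linear projection on the controls (with intercept), on pairwise-complete
    cases.  The p value uses t = r sqrt(df/(1-r^2)) with df = n - 2 - #controls.
    """
    ctrl = controls.to_frame() if isinstance(controls, pd.Series) else controls
    if ctrl.shape[1] == 0:
        # no controls: the partial correlation is the plain coefficient
        return pairwise_corr(x, y, "pearson")
    cols = _complete(x, y, *[ctrl[c] for c in ctrl.columns])
    xa, ya, zs = cols[0], cols[1], np.column_stack(cols[2:])
    n, k = len(xa), zs.shape[1]
    if n <= k + 2:
        raise ValueError("too few complete cases for the control set")
    design = np.column_stack([np.ones(n), zs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular control set")
    beta_x, *_ = np.linalg.lstsq(design, xa, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ya, rcond=None)
    rx = xa - design @ beta_x
    ry = ya - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return AssociationResult(
        str(x.name), str(y.name), "partial", r, n, float(p),
        controls=tuple(str(c) for c in ctrl.columns),
    )


def average_performance_composite(
    battery: pd.DataFrame,
    exclude: Sequence[str] = (),
    sign_map: Mapping[str, int] | None = None,
) -> pd.Series:
    """Mean of z-standardized battery scores per participant.

    Each remaining test is z-standardized within the cohort and direction-
    aligned via ``sign_map`` (+1 higher = better, -1 higher = worse, e.g.
    error counts); the composite is the row mean over non-missing components.
    Tests named in ``exclude`` (the outcome under evaluation and the
    navigation score itself) are left out.
    """
    cols = [c for c in battery.columns if c not in set(exclude)]
    if len(cols) < 2:
        raise ValueError("composite needs at least two component tests")
    signs = {c: (sign_map or {}).get(c, 1) for c in cols}
    z = pd.DataFrame(index=battery.index)
    for c in cols:
        col = battery[c].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"component {c!r} has zero variance")
        z[c] = signs[c] * (col - col.mean()) / sd
    comp = z.mean(axis=1, skipna=True)
    comp[z.isna().all(axis=1)] = np.nan
    comp.name = "average_performance"
    return comp


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (original order)."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p values must lie in [0, 1]")
    if arr.size == 1:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


def ttest_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance independent-samples t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return 0.0, df, 1.0
        return float("inf") if m1 > m2 else float("-inf"), df, 0.0
    t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(t), df, float(p)


def levene_check(*groups: Sequence[float], alpha: float = 0.05) -> tuple[bool, float, float]:
    """Levene's test on absolute deviations from group means.

    Returns (homogeneous, W statistic, p); homogeneous iff p >= alpha.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    if all(a.std() == 0 for a in arrays):
        return True, 0.0, 1.0
    w, p = stats.levene(*arrays, center="mean")
    return bool(p >= alpha), float(w), float(p)


def clogg_z(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Z test for the difference of two regression coefficients.

    Z = (b1 - b2) / sqrt(se1^2 + se2^2), two-tailed p from the standard
    normal; used to compare an effect before and after partialling.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def association_battery(
    data: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    age: str | None = "age",
    composite_components: Sequence[str] | None = None,
    sign_map: Mapping[str, int] | None = None,
    bh_family: str = "per_column",
) -> pd.DataFrame:
    """Correlation table of the outcome with each covariate.

    For every variable: the plain coefficient (Pearson/Spearman chosen by the
    normality rule), the partial correlation controlling for age, and the
    partial correlation controlling for the average-performance composite
    over ``composite_components`` minus the variable itself.  BH adjustment
    is applied either within each coefficient column (``per_column``) or over
    all tests pooled (``pooled``) — the family definition is a configuration
    choice.
    """
    if bh_family not in ("per_column", "pooled"):
        raise ValueError("bh_family must be 'per_column' or 'pooled'")
    out_diag = describe(data[outcome].dropna())
    rows = []
    for var in variables:
        v_diag = describe(data[var].dropna())
        kind = choose_coefficient(out_diag, v_diag)
        plain = pairwise_corr(data[var], data[outcome], kind)
        row: dict = {
            "variable": var,
            "kind": kind,
            "r": plain.estimate,
            "n": plain.n,
            "p": plain.p,
        }
        if age is not None and var != age:
            part = partial_corr(data[var], data[outcome], data[age])
            row.update(r_age=part.estimate, n_age=part.n, p_age=part.p)
        if composite_components and var in composite_components:
            comp = average_performance_composite(
                data[list(composite_components)],
                exclude=[var, outcome],
                sign_map=sign_map,
            )
            part = partial_corr(data[var], data[outcome], comp)
            row.update(r_comp=part.estimate, n_comp=part.n, p_comp=part.p)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variable")
    pcols = [c for c in ("p", "p_age", "p_comp") if c in table.columns]
    if bh_family == "per_column":
        for c in pcols:
            mask = table[c].notna()
            table.loc[mask, c + "_adj"] = bh_adjust(table.loc[mask, c].to_numpy())
    else:
        stacked = table[pcols].stack()
        adj = pd.Series(bh_adjust(stacked.to_numpy()), index=stacked.index)
        for c in pcols:
            table[c + "_adj"] = adj.xs(c, level=1).reindex(table.index)
    return table
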