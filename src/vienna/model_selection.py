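"""Forced-entry regression and two-stage predictor reduction.

The validation workflow regresses the navigation score on all domain-
specific covariates that were individually significant (forced entry), then
searches for a parsimonious model in two ways and checks that they agree:

1. *p-based backward reduction* — refit keeping only predictors whose p value
   is below a liberal threshold (default .10; tightened to .05 when the
   liberal threshold would drop nothing), stopping when a nested-model F test
   shows the reduced model explains significantly less variance (the previous
   model is then kept) or when every retained predictor is significant;
2. *AIC backward selection* — greedily drop the predictor whose removal most
   lowers the AIC until no drop improves it.

Predictors are z-standardized by default so coefficients are comparable
across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionModel",
    "ReductionStep",
    "ReductionTrace",
    "forced_entry_ols",
    "nested_anova",
    "reduce_by_p",
    "aic_backward",
]


@dataclass(frozen=True)
class RegressionModel:
    outcome: str
    predictors: tuple[str, ...]
    coef: pd.DataFrame  # per-term: b, ci_low, ci_high, t, p
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    n: int
    aic: float
    ssr: float  # residual sum of squares


@dataclass(frozen=True)
class ReductionStep:
    dropped: tuple[str, ...]
    rule: str
    delta_r2: float = float("nan")
    f: float = float("nan")
    p: float = float("nan")


@dataclass(frozen=True)
class ReductionTrace:
    steps: tuple[ReductionStep, ...]
    final: RegressionModel
    stop_reason: str
    models: tuple[RegressionModel, ...] = field(default_factory=tuple)


def _design(
    y: pd.Series, X: pd.DataFrame, standardize: bool
) -> tuple[pd.Series, pd.DataFrame]:
    df = pd.concat([y, X], axis=1).dropna()
    yv = df[y.name]
    Xv = df[X.columns].astype(float)
    const = [c for c in Xv.columns if Xv[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant predictor(s): {const}")
    if standardize:
        Xv = (Xv - Xv.mean()) / Xv.std(ddof=1)
    return yv, Xv


def forced_entry_ols(
    y: pd.Series, X: pd.DataFrame, standardize: bool = True
) -> RegressionModel:
    """OLS with all predictors entered simultaneously.

    With ``standardize=True`` (default) predictors are z-scored so the
    reported b are on the standardized-predictor scale.
    """
    if len(X.columns) == 0:
        raise ValueError("need at least one predictor")
    yv, Xv = _design(y, X, standardize)
    n, p = Xv.shape
    if n <= p + 1:
        raise ValueError(f"n = {n} too small for {p} predictors")
    design = sm.add_constant(Xv)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = Xv.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; check collinear columns {worst}")
    fit = sm.OLS(yv, design).fit()
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "b": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return RegressionModel(
        outcome=str(y.name),
        predictors=tuple(X.columns),
        coef=coef,
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=n,
        aic=float(fit.aic),
        ssr=float(fit.ssr),
    )


def nested_anova(
    full: RegressionModel, reduced: RegressionModel
) -> tuple[float, float, float]:
    """Nested-model F test: (delta R^2, F, p).

    ``F = (dSSR / ddf) / (SSE_full / df_full)`` where dSSR is the increase in
    residual sum of squares from dropping the predictors.
    """
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    if reduced.n != full.n:
        raise ValueError("models were fit on different cases")
    ddf = full.df_model - reduced.df_model
    delta_r2 = full.r_squared - reduced.r_squared
    if ddf == 0:
        return 0.0, 0.0, 1.0
    f = ((reduced.ssr - full.ssr) / ddf) / (full.ssr / full.df_resid)
    p = stats.f.sf(f, ddf, full.df_resid)
    return float(delta_r2), float(f), float(p)


def reduce_by_p(
    y: pd.Series,
    X: pd.DataFrame,
    keep_threshold: float = 0.10,
    fallback: float = 0.05,
    alpha: float = 0.05,
    standardize: bool = True,
) -> ReductionTrace:
    """Backward reduction retaining predictors with p below the threshold.

    At each step the model is refit on the predictors with p < keep_threshold
    in the current model; when that drops nothing, the stricter ``fallback``
    threshold is tried once.  Reduction stops when every retained predictor is
    significant at ``alpha``, or when the nested F test says the reduced model
    explains significantly less variance (then the pre-reduction model is
    returned with stop reason ``delta R2 significant``).
    """
    # fit all candidate models on the same complete cases
    cases = pd.concat([y, X], axis=1).dropna().index
    yv, Xv = y.loc[cases], X.loc[cases]
    current = forced_entry_ols(yv, Xv, standardize)
    steps: list[ReductionStep] = []
    models = [current]
    while True:
        pvals = current.coef["p"].drop("const")
        if (pvals < alpha).all():
            return ReductionTrace(
                tuple(steps), current, "all predictors significant", tuple(models)
            )
        keep = pvals.index[pvals < keep_threshold]
        rule = f"p < {keep_threshold}"
        if len(keep) == len(pvals):
            keep = pvals.index[pvals < fallback]
            rule = f"p < {fallback} (fallback)"
        if len(keep) == len(pvals):
            return ReductionTrace(
                tuple(steps), current, "no predictor removable", tuple(models)
            )
        if len(keep) == 0:
            return ReductionTrace(
                tuple(steps), current, "all predictors would be dropped", tuple(models)
            )
        reduced = forced_entry_ols(yv, Xv[list(keep)], standardize)
        dropped = tuple(sorted(set(pvals.index) - set(keep)))
        d_r2, f, p = nested_anova(current, reduced)
        steps.append(ReductionStep(dropped, rule, d_r2, f, p))
        if p < alpha:
            return ReductionTrace(
                tuple(steps), current, "delta R2 significant", tuple(models)
            )
        current = reduced
        models.append(current)


def aic_backward(
    y: pd.Series, X: pd.DataFrame, standardize: bool = True
) -> RegressionModel:
    """Backward stepwise selection minimizing the AIC.

    Repeatedly removes the predictor whose removal lowers the (Gaussian
    log-likelihood) AIC the most; stops when no removal improves it.  May end
    at the intercept-only model for pure-noise predictors.
    """
    cases = pd.concat([y, X], axis=1).dropna().index
    yv = y.loc[cases]
    Xv = X.loc[cases]

    def fit_aic(cols: list[str]) -> float:
        if not cols:
            return float(sm.OLS(yv.astype(float), np.ones(len(yv))).fit().aic)
        return forced_entry_ols(yv, Xv[cols], standardize).aic

    cols = list(X.columns)
    best = fit_aic(cols)
    while cols:
        candidates = [(fit_aic([c for c in cols if c != drop]), drop) for drop in cols]
        new_aic, drop = min(candidates)
        if new_aic >= best:
            break
        best = new_aic
        cols.remove(drop)
    if not cols:
        fit = sm.OLS(yv.astype(float), np.ones(len(yv))).fit()
        coef = pd.DataFrame(
            {"b": fit.params, "ci_low": fit.conf_int()[0],
             "ci_high": fit.conf_int()[1], "t": fit.tvalues, "p": fit.pvalues}
        )
        coef.index = ["const"]
        return RegressionModel(
            str(y.name), (), coef, float(fit.rsquared), float("nan"),
            0, int(fit.df_resid), len(yv), float(fit.aic), float(fit.ssr),
        )
    return forced_entry_ols(yv, Xv[cols], standardize)
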