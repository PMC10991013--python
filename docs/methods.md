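# Methods

This note documents the statistical procedures the package implements, the
numerical choices behind them, what the synthetic-cohort generator does and
does not emulate, and known limitations.

## Scoring model

Each VIENNA item is a forced choice among the `n_doors` doors of a hallway.
The rubric is a partition of the doors: the correct door (2 points, no
error), the updating set — doors parallel or adjacent to the correct one
(1 point, spatial-updating error), the rotation set — the door(s) opposite
(1 point, perspective-rotation error), and the remainder (0 points, "other").
Door geometry is configuration, not computation: the package never derives
door sets from 3-D layouts, because layouts are distributed with the test
materials, not in the literature. The total score is the sum over the 12
main items (0–24); practice items carry `is_main=False` and are ignored by
totals. A missing response to a main item scores 0/"other" with a logged
warning — under standardized administration premature terminations do not
occur, so no refusal code exists.

The chance-expected item score is `E = (2·1 + 1·m) / n_doors` for `m`
one-point doors, kept as an exact rational until report time. The
difficulty ratio M̄/E makes items with different door counts comparable
(1 = chance, larger = easier). When reproducing published item tables, E is
taken from the published values (2 dp) rather than recomputed from door
counts, since the published geometry is not public; the full-turn items,
where both routes coincide, validate this convention.

## Wilson's e

Discrimination uses the corrected (rest-score) item–total correlation
measured with Wilson's e. Over all n(n−1)/2 observation pairs, with C
concordant, D discordant, T_x tied on the item only, T_y tied on the
rest-score only, and T_xy tied on both,

    e = (C − D) / (C + D + T_x + T_y),

i.e. only doubly-tied pairs leave the denominator. Consequences worth
noting: with no ties at all, e equals Kendall's τ-a; a zero-variance item
yields e = 0 (the denominator is all T_x), which is exactly what the
published item table shows for an item solved by every participant. The
implementation is a vectorized O(n²) pair count; an independent loop-based
pair classifier guards it in the test suite.

## Polychoric correlations and ordinal alpha

Ordinal 0/1/2 item scores are modeled as discretized standard-normal latent
variables. Estimation is the classical two-step procedure: thresholds are
fixed at Φ⁻¹ of the cumulative margins, then the latent correlation ρ
maximizes the multinomial log-likelihood with cell probabilities given by
bivariate-normal rectangle integrals. Two-step (rather than joint) ML is
standard, much faster, and adequate at n ≈ 79. Numerical choices:

* the bivariate normal CDF is evaluated with an Owen's-T decomposition
  (machine precision against quadrature, and fast enough for bootstrap);
* ρ is optimized by bounded Brent search on [−0.999, 0.999] (xatol 1e−6);
  the bound keeps the likelihood finite for perfectly monotone tables;
* empty interior cells get no continuity correction — the likelihood handles
  zero counts, and cell probabilities are floored at 1e−300;
* categories with zero margin are dropped; an item with a single occupied
  category is flagged zero-variance and excluded before estimation.

The pairwise matrix need not be positive semi-definite at small n; it is
repaired by eigenvalue clipping (floor 1e−8) with diagonal renormalization,
and the repair is logged. Ordinal alpha is then
`α = (k/(k−1))(1 − k/S)` with S the sum of all matrix entries, equivalent to
`k·r̄/(1+(k−1)·r̄)`; S ≤ 0 makes alpha undefined (reported missing).
`alpha_pipeline` always excludes zero-variance items and optionally all
items with variance ≤ a threshold (the published analysis used > 0.05). The
95% CI is a percentile bootstrap over participants (default 1000 resamples,
seeded); the CI construction of the original analysis is unspecified, so
published CI bounds are not reproduction targets. Bootstrap draws whose
resample degenerates (an item losing all variance) are skipped rather than
re-specified.

## Distribution diagnostics

Skewness and excess kurtosis use the adjusted Fisher–Pearson estimators
(G1, G2) with the exact small-sample standard errors

    SE(γ₁) = sqrt(6n(n−1) / ((n−2)(n+1)(n+3)))
    SE(γ₂) = sqrt(24n(n−1)² / ((n−3)(n−2)(n+3)(n+5)))

and a variable counts as normal when both |z| = |γ/SE| are strictly below
3.29, the medium-sample threshold. This estimator pair reproduces the
published z-scores from the published shape statistics (±0.02, the slack of
2-dp input rounding); the published total-score pair (γ₁ = −0.29,
z = −1.05) is internally inconsistent beyond that slack (−0.29/SE = −1.07)
and evidently derives from the unrounded statistic. MAD is reported raw —
no 1.4826 consistency factor — matching neuropsychological descriptive
convention (configurable downstream).

Outlier rules: (1) the adjusted boxplot with fences
`[Q1 − 1.5·e^(−4MC)·IQR, Q3 + 1.5·e^(3MC)·IQR]` for medcouple MC ≥ 0 (the
exponents swap to −3/4 for MC < 0), which reduces exactly to Tukey's rule
at MC = 0; and (2) the mean ± 2.5 SD rule used for the roughly symmetric
total score. The medcouple is computed via statsmodels (O(n²) kernel
median, −1/0/+1 special kernel for median ties); a hand-rolled enumeration
oracle verifies it in the tests. Quartiles use linear interpolation, a
convention the adjusted-boxplot literature does not pin down, so it is
stated here. Note one fact the tests document: a single extreme value in an
otherwise symmetric sample leaves MC at 0 — MC measures skewness of the
bulk, not the presence of an outlier; the fences still flag the value.

## Association battery

Pearson's r is used when both variables pass the 3.29 rule, Spearman's rho
otherwise. Partial correlations are Pearson correlations of OLS residuals
after projecting both variables on the controls (with intercept); with one
control this equals the textbook recursive formula, and with none it
degrades to the plain coefficient. p-values use t = r·sqrt(df/(1−r²)),
df = n − 2 − #controls. The average-performance composite z-standardizes
each battery test within the cohort, aligns directions via a configurable
sign map (error counts and reaction times count as "higher = worse"), and
averages over non-missing components, excluding the navigation score and
the test under evaluation. Missing data are never imputed — every analysis
is pairwise-complete and reports its n. Benjamini–Hochberg correction is
applied per coefficient column by default; pooling all tests into one
family is a configuration option because the original family definition is
not stated. BH output is monotone in input ranks and never below the raw
p, but it is *not* idempotent — re-adjusting adjusted values inflates them,
so adjusted p-values must not be fed back into the procedure. Group
comparisons use the pooled-variance t-test (also available from summary
statistics alone, for pilot-style comparisons) guarded by Levene's test on
absolute deviations from group means; coefficient differences use Clogg's
Z = (b₁−b₂)/sqrt(se₁²+se₂²).

## Regression and predictor reduction

The forced-entry model enters all candidate predictors simultaneously;
predictors are z-standardized by default so coefficients are comparable
across instruments (raw scale available). Reduction retains predictors with
p below a liberal threshold (.10), tightening once to .05 when the liberal
screen would drop nothing, and stops when every retained predictor is
significant at .05 or when the nested-model F test
`F = (ΔSSR/Δdf)/(SSE_full/df_full)` shows the reduction lost significant
variance (the pre-reduction model is then restored). The published wording
("excluding predictors with a p value below .1") contradicts the model it
actually built — the four predictors *with* p < .1 were kept — so the
retain-if-p-below-threshold reading is implemented. AIC backward selection
(Gaussian log-likelihood AIC, consistent constants) serves as a
cross-check.

A structural fact the tests encode: with this stop rule, a null predictor
survives the final screen with probability ≈ α, so with five null
candidates the *exact* active set is recovered in about 0.95⁵ ≈ 77% of
replicates even when every true effect is found; recovery of the true
predictors themselves (containment) is essentially certain at the tested
effect sizes. AIC's implicit keep threshold (p ≈ .157) is more liberal
still, so the two paths agree on the true actives far more often than on
the exact set.

## Synthetic cohorts

The generator emulates the validation study's structure: n = 79, ages
uniform on 50–85, latent ability θ = β_age·z(age) + ε (β_age = −0.75,
σ_ε = 1, giving corr(age, θ) = −0.6 and a realized age–total correlation
near −0.5), item success P(correct|θ) = logistic(a(θ − b)) with a = 1.1,
and two deficit traits (loading −0.4 on θ) that route errors to rotation
vs. updating vs. zero-point doors through exponential class weights
(rotation boost 1.6, updating boost 2.3, trait gain 0.8), uniform within a
class. Item difficulties b are set by inverting the logistic-normal
mean-probability approximation at per-item success targets taken from the
published frequencies, except that three items are nudged (i9 easier, i10
and i12 slightly harder) so mean b is non-decreasing over turn types — a
config invariant the raw published pattern violates (the original item 9 is
anomalously hard for its type). Door layouts are synthetic stand-ins whose
chance-expected scores match the published per-item E at 2 dp.

Defaults were calibrated once, before being frozen, to the published
marginal pattern: cohort-mean total ≈ 19.4 (SD ≈ 3) in the upper score
range without floor effects, rotation errors ≈ 1.5 and updating errors
≈ 0.55 per participant with a right-skewed updating distribution (median 0,
about 11% of participants with more than one updating error). The
covariate battery loads each simulated test on θ and age with test-specific
noise, direction flips for complaint/speed instruments, and the observed
missingness rates (3/79, 4/79, 1/79 for the depression scale, mental
rotation, and perspective-taking tests). Draws use spawned substreams per
block (traits, items, covariates, missingness), so extending one block
never perturbs another, and chosen doors are always scored through the
scoring module.

What the generator does **not** emulate: multidimensional item structure
(one latent trait only — real no-turn items may tap a separate vista-space
factor), local item dependence, response times, systematic (non-random)
missingness mechanisms, and the discreteness artifacts of real
questionnaire scales (covariates are Gaussian on a z-scale). Passing tests
therefore certify the pipeline's statistical machinery and its behavior
under the intended data shape, not the psychometrics of the real
instrument.

## Problem sizes in tests and the acceptance script

Deterministic reproductions run on the published tables directly. Monte
Carlo checks use sizes at which the targeted behavior is well separated
from noise while keeping the suite quick: polychoric recovery at n = 5000
(tolerance ±0.05), backward-elimination recovery over 60–100 replicates of
n = 200, generator calibration over 100–150 cohorts of n = 79, and
bootstrap CIs at 10–200 resamples in pipeline smoke tests (the library
default is 1000).

## Known limitations

* Polychoric estimation is pairwise two-step; no joint ML, no standard
  errors for ρ, and the PSD repair slightly shrinks extreme entries.
* Wilson's e p-values are not computed (the original analysis reports none
  at item level).
* The published association/regression coefficient values require the raw
  cohort and are out of reach by design; synthetic cohorts reproduce
  sign and ordering structure instead.
* Factor-structure analysis (multidimensionality) is deliberately out of
  scope, as in the original evaluation.
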