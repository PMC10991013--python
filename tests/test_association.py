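"""Correlation battery: coefficient choice, partials, composites, BH, tests."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from vienna.association import (
    association_battery,
    average_performance_composite,
    bh_adjust,
    choose_coefficient,
    clogg_z,
    levene_check,
    pairwise_corr,
    partial_corr,
    ttest_from_summary,
)
from vienna.diagnostics import describe


@pytest.fixture(scope="module")
def normal_diag():
    rng = np.random.default_rng(0)
    return describe(rng.normal(size=500))


@pytest.fixture(scope="module")
def skewed_diag():
    rng = np.random.default_rng(1)
    return describe(rng.exponential(size=500) ** 2)


class TestChooseCoefficient:
    def test_both_normal_pearson(self, normal_diag):
        assert choose_coefficient(normal_diag, normal_diag) == "pearson"

    def test_one_skewed_spearman(self, normal_diag, skewed_diag):
        assert choose_coefficient(normal_diag, skewed_diag) == "spearman"
        assert choose_coefficient(skewed_diag, normal_diag) == "spearman"

    def test_both_skewed_spearman(self, skewed_diag):
        assert choose_coefficient(skewed_diag, skewed_diag) == "spearman"


def _toy(n=120, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    x = 0.6 * z + rng.normal(size=n)
    y = -0.5 * z + rng.normal(size=n)
    return pd.DataFrame({"x": x, "y": y, "z": z, "w": rng.normal(size=n)})


class TestPartialCorr:
    def test_recursive_formula_single_control(self):
        df = _toy()
        r = df.corr()
        want = (r.loc["x", "y"] - r.loc["x", "z"] * r.loc["y", "z"]) / np.sqrt(
            (1 - r.loc["x", "z"] ** 2) * (1 - r.loc["y", "z"] ** 2)
        )
        got = partial_corr(df["x"], df["y"], df["z"])
        assert got.estimate == pytest.approx(want, abs=1e-10)

    def test_matches_pingouin(self):
        df = _toy(seed=5)
        ours = partial_corr(df["x"], df["y"], df[["z", "w"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z", "w"])
        assert ours.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_residualization_oracle(self):
        df = _toy(seed=7)
        design = np.column_stack([np.ones(len(df)), df["z"], df["w"]])
        rx = df["x"] - design @ np.linalg.lstsq(design, df["x"], rcond=None)[0]
        ry = df["y"] - design @ np.linalg.lstsq(design, df["y"], rcond=None)[0]
        want = stats.pearsonr(rx, ry)[0]
        got = partial_corr(df["x"], df["y"], df[["z", "w"]]).estimate
        assert got == pytest.approx(want, abs=1e-10)

    def test_irrelevant_control_leaves_estimate(self):
        df = _toy(seed=9)
        plain = pairwise_corr(df["x"], df["y"]).estimate
        part = partial_corr(df["x"], df["y"], df["w"]).estimate
        assert part == pytest.approx(plain, abs=0.05)

    def test_empty_control_set_is_plain_coefficient(self):
        df = _toy(seed=11)
        plain = pairwise_corr(df["x"], df["y"]).estimate
        part = partial_corr(df["x"], df["y"], df[[]])
        assert part.estimate == pytest.approx(plain)

    def test_singular_controls_rejected(self):
        df = _toy(seed=13)
        df["z2"] = df["z"] * 2
        with pytest.raises(ValueError, match="singular"):
            partial_corr(df["x"], df["y"], df[["z", "z2"]])

    def test_pairwise_complete_n_reported(self):
        df = _toy(seed=15)
        df.loc[df.index[:10], "x"] = np.nan
        res = partial_corr(df["x"], df["y"], df["z"])
        assert res.n == len(df) - 10


class TestComposite:
    def test_one_sd_on_both_components(self):
        base = pd.DataFrame(
            {"t1": [0.0, 1, -1, 2, -2], "t2": [0.0, 2, -2, 4, -4]}
        )
        comp = average_performance_composite(base)
        # participant 3 sits at +sqrt(2) SD... compute directly instead:
        z = (base - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(comp, z.mean(axis=1))

    def test_exclusion_removes_evaluated_test(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)),
                          columns=["vienna", "a", "b", "c"])
        comp_all = average_performance_composite(df, exclude=["vienna"])
        comp_wo_a = average_performance_composite(df, exclude=["vienna", "a"])
        assert not np.allclose(comp_all, comp_wo_a)

    def test_sign_map_flips_direction(self):
        df = pd.DataFrame({"good": [1.0, 2, 3, 4], "errors": [1.0, 2, 3, 4]})
        comp = average_performance_composite(df, sign_map={"errors": -1})
        np.testing.assert_allclose(comp, 0.0, atol=1e-12)

    def test_missing_components_skipped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [2.0, 4, 6, 8]})
        comp = average_performance_composite(df)
        assert not np.isnan(comp.iloc[3])

    def test_zero_variance_component_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="zero variance"):
            average_performance_composite(df)

    def test_correlation_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=50), name="y")
        c1 = average_performance_composite(df)
        df2 = df.copy()
        df2["b"] = 10.0 * df2["b"] - 3.0
        c2 = average_performance_composite(df2)
        assert stats.pearsonr(c1, y)[0] == pytest.approx(
            stats.pearsonr(c2, y)[0], abs=1e-12
        )


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rank_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        adj = bh_adjust(p)
        assert (adj >= p).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTTestFromSummary:
    def test_pilot_groups_do_not_differ(self):
        # virtual reconstruction vs refined adaptation, from group summaries
        t, df, p = ttest_from_summary(16.86, 3.08, 14, 16.59, 2.62, 17)
        assert df == 29
        assert round(t, 2) == 0.26
        # the published p (.795) stems from unrounded group summaries; the
        # 2 dp summaries reproduce it to within one unit in the last place
        assert p == pytest.approx(0.795, abs=0.002)

    def test_equal_means(self):
        t, _, p = ttest_from_summary(5, 1, 10, 5, 1, 10)
        assert (t, p) == (0.0, 1.0)

    def test_matches_raw_data_pooled_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 55)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_sum, _, p_sum = ttest_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_degenerate_variance(self):
        t, _, p = ttest_from_summary(5, 0, 5, 6, 0, 5)
        assert np.isinf(t) and p == 0.0


class TestLevene:
    def test_identical_groups_homogeneous(self):
        ok, _, p = levene_check([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert ok and p == pytest.approx(1.0)

    def test_unequal_variances_detected(self):
        rng = np.random.default_rng(7)
        ok, _, p = levene_check(rng.normal(0, 1, 50), rng.normal(0, 5, 50))
        assert not ok and p < 0.01

    def test_two_group_df_structure(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(size=25)
        _, w, p = levene_check(a, b)
        assert p == pytest.approx(stats.f.sf(w, 1, len(a) + len(b) - 2))

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            levene_check([1.0], [1.0, 2.0])


class TestCloggZ:
    def test_equal_coefficients(self):
        z, p = clogg_z(0.4, 0.1, 0.4, 0.2)
        assert z == 0.0 and p == 1.0

    def test_formula_value(self):
        z, _ = clogg_z(0.5, 0.1, 0.2, 0.1)
        assert z == pytest.approx(0.3 / np.sqrt(0.02))

    def test_larger_ses_shrink_z(self):
        z1, _ = clogg_z(0.5, 0.1, 0.2, 0.1)
        z2, _ = clogg_z(0.5, 0.3, 0.2, 0.3)
        assert abs(z2) < abs(z1)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            clogg_z(0.5, 0.0, 0.2, 0.1)


def test_association_battery_structure(default_cohort):
    cov = default_cohort.covariates
    battery = ["age", "mmse", "ptsot", "fpt_productivity", "gds"]
    tab = association_battery(
        cov,
        outcome="vienna_total",
        variables=battery,
        age="age",
        composite_components=["mmse", "ptsot", "fpt_productivity",
                              "rocf_copy", "block_span_backward"],
        sign_map={"gds": -1},
    )
    assert list(tab.index) == battery
    assert (tab["p_adj"] >= tab["p"] - 1e-12).all()
    # pairwise-complete n respects missingness (gds has missing cells)
    assert tab.loc["gds", "n"] <= len(cov)
    # age controls itself is meaningless and therefore absent
    assert np.isnan(tab.loc["age", "r_age"])
    # the configured age effect is negative and strong
    assert tab.loc["age", "r"] < -0.25
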