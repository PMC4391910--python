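import numpy as np
import pandas as pd
import pytest

from statincf.contribution import (
    AgeCurve,
    build_age_curve,
    contribution_point,
    contribution_ui,
    estimate_contribution,
    integration_weights,
    sensitivity_inflate,
    spline_area_between,
    stratified_contribution,
)
from statincf.counterfactual import apply_no_statins_scenario
from statincf.effects import PooledEffect
from statincf.survey_io import PERIOD_1991, PERIOD_2011

from conftest import make_participants


def flat_curve(value, lo=18, hi=89, se=0.0, label=""):
    ages = np.arange(lo, hi + 1)
    return AgeCurve(
        label=label, ages=ages, mean=np.full(len(ages), float(value)),
        se=np.full(len(ages), float(se)), n=np.full(len(ages), 100),
    )


def curve_from_fn(fn, lo=18, hi=89, se=0.0):
    ages = np.arange(lo, hi + 1)
    return AgeCurve(
        label="fn", ages=ages, mean=fn(ages.astype(float)),
        se=np.full(len(ages), float(se)), n=np.full(len(ages), 100),
    )


class TestSplineArea:
    def test_identical_curves_zero_area(self):
        c = curve_from_fn(lambda a: 5 + 0.01 * a)
        assert spline_area_between(c, c, 18, 89) == pytest.approx(0.0, abs=1e-12)

    def test_constant_gap_rectangle(self):
        upper, lower = flat_curve(5.5), flat_curve(5.0)
        assert spline_area_between(upper, lower, 18, 89) == pytest.approx(35.5)

    def test_quadratic_curves_match_analytic_integral(self):
        # natural cubic splines reproduce these quadratics away from the
        # boundary; compare on an interior window against the closed form
        f = lambda a: 6.0 + 0.02 * (a - 50) - 1e-4 * (a - 50) ** 2
        g = lambda a: 5.0 + 0.01 * (a - 50)
        F = lambda a: 6 * a + 0.01 * (a - 50) ** 2 - 1e-4 / 3 * (a - 50) ** 3
        G = lambda a: 5 * a + 0.005 * (a - 50) ** 2
        analytic = (F(80) - F(25)) - (G(80) - G(25))
        got = spline_area_between(curve_from_fn(f), curve_from_fn(g), 25, 80)
        assert got == pytest.approx(analytic, rel=1e-6)

    def test_signed_area_cancels(self):
        upper = curve_from_fn(lambda a: 5 + 0.01 * (a - 53.5))
        lower = flat_curve(5.0)
        # antisymmetric gap around the midpoint integrates to ~0
        assert spline_area_between(upper, lower, 18, 89) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_area_additivity_over_subranges(self):
        rng = np.random.default_rng(0)
        ages = np.arange(18, 90)
        c1 = AgeCurve("a", ages, rng.normal(5.5, 0.3, len(ages)),
                      np.zeros(len(ages)), np.full(len(ages), 10))
        c2 = flat_curve(5.0)
        whole = spline_area_between(c1, c2, 18, 89)
        parts = spline_area_between(c1, c2, 18, 55) + spline_area_between(
            c1, c2, 55, 89
        )
        assert whole == pytest.approx(parts, rel=1e-9)

    def test_range_must_be_covered(self):
        c = flat_curve(5.0, lo=30, hi=80)
        with pytest.raises(ValueError, match="cover"):
            spline_area_between(c, c, 18, 89)

    def test_integration_weights_exact_for_cubics(self):
        ages = np.arange(18, 90).astype(float)
        w = integration_weights(ages, 18, 89)
        # linear functions are integrated exactly by any spline rule
        assert w @ ages == pytest.approx((89**2 - 18**2) / 2, rel=1e-12)
        assert w.sum() == pytest.approx(71.0, rel=1e-12)


class TestContributionPoint:
    def test_no_statins_equal_recent_gives_zero(self):
        c91, c11 = flat_curve(5.9), flat_curve(5.2)
        _, _, frac = contribution_point(c91, c11, c11, 18, 89)
        assert frac == pytest.approx(0.0, abs=1e-12)

    def test_no_statins_equal_baseline_gives_one(self):
        c91, c11 = flat_curve(5.9), flat_curve(5.2)
        _, _, frac = contribution_point(c91, c11, c91, 18, 89)
        assert frac == pytest.approx(1.0, rel=1e-12)

    def test_constant_gap_ratio(self):
        c11 = flat_curve(5.17)
        c91 = flat_curve(5.17 + 0.69)
        cns = flat_curve(5.17 + 0.23)
        area_a, area_b, frac = contribution_point(c91, c11, cns, 18, 89)
        assert area_a == pytest.approx(0.69 * 71)
        assert area_b == pytest.approx(0.23 * 71)
        assert frac == pytest.approx(0.23 / 0.69, rel=1e-9)

    def test_zero_area_a_rejected(self):
        c = flat_curve(5.0)
        with pytest.raises(ValueError, match="undefined"):
            contribution_point(c, c, flat_curve(5.3), 18, 89)


class TestBuildAgeCurve:
    def test_everyone_above_top_age_pools_into_top_bin(self):
        df = make_participants(n=120, seed=1)
        df["age"] = np.random.default_rng(0).integers(90, 96, len(df))
        with pytest.raises(ValueError, match="age 18"):
            build_age_curve(df, age_range=(18, 89))
        curve = build_age_curve(df, age_range=(89, 89))
        assert curve.ages.tolist() == [89]
        assert curve.n[0] == df["tc_mmol"].notna().sum()

    def test_single_participant_per_age_reproduces_values(self):
        ages = np.arange(18, 90)
        df = make_participants(n=len(ages), seed=2)
        df["age"] = ages
        df["weight"] = 1.0
        df["tc_mmol"] = 5 + 0.01 * ages
        curve = build_age_curve(df, age_range=(18, 89), min_n=2)
        np.testing.assert_allclose(curve.mean, 5 + 0.01 * ages, rtol=1e-12)
        assert curve.sparse_ages == list(range(18, 90))


def scenario_population(n=4000, seed=0, prevalence=0.25, e=0.257):
    """Two-period population with a known multiplicative effect applied."""
    rng = np.random.default_rng(seed)
    d91 = make_participants(n=n, period=PERIOD_1991, seed=seed, prevalence=0.0,
                            tc_mean=5.9)
    d11 = make_participants(n=n, period=PERIOD_2011, seed=seed + 1,
                            prevalence=prevalence, tc_mean=5.45)
    users = d11["statin_user"] & d11["tc_mmol"].notna()
    d11.loc[users, "tc_mmol"] *= 1 - e
    df = pd.concat([d91, d11], ignore_index=True)
    df["age"] = rng.integers(18, 96, len(df))
    return df


class TestEstimateContribution:
    def test_ui_contains_point(self):
        df = scenario_population(seed=3)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        est = estimate_contribution(scen, n_draws=500, seed=1)
        assert est.ui_low <= est.point <= est.ui_high

    def test_deterministic_given_seed(self):
        df = scenario_population(seed=4)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        a = estimate_contribution(scen, n_draws=400, seed=9)
        b = estimate_contribution(scen, n_draws=400, seed=9)
        assert (a.point, a.ui_low, a.ui_high) == (b.point, b.ui_low, b.ui_high)

    def test_point_recomputable_from_areas(self):
        df = scenario_population(seed=5)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        est = estimate_contribution(scen, n_draws=200, seed=2)
        assert est.point == pytest.approx(est.area_b / est.area_a, rel=1e-12)

    def test_vertical_translation_invariance(self):
        df = scenario_population(seed=6)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        est1 = estimate_contribution(scen, n_draws=200, seed=3)
        shifted = scen.copy()
        shifted["tc_mmol"] = shifted["tc_mmol"] + 1.0
        shifted["tc_scenario"] = shifted["tc_scenario"] + 1.0
        est2 = estimate_contribution(shifted, n_draws=200, seed=3)
        assert est2.point == pytest.approx(est1.point, rel=1e-9)

    def test_zero_prevalence_gives_zero_contribution(self):
        df = scenario_population(seed=7, prevalence=0.0)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        est = estimate_contribution(scen, n_draws=200, seed=4)
        assert est.point == pytest.approx(0.0, abs=1e-12)
        assert est.area_b == pytest.approx(0.0, abs=1e-12)

    def test_independent_mode_wider_than_linked(self):
        df = scenario_population(seed=8, n=6000)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        linked = estimate_contribution(scen, n_draws=2000, seed=5, mode="linked")
        indep = estimate_contribution(scen, n_draws=2000, seed=5,
                                      mode="independent")
        assert (indep.ui_high - indep.ui_low) > (linked.ui_high - linked.ui_low)
        assert indep.point == pytest.approx(linked.point, rel=1e-12)

    def test_scenario_column_required(self):
        df = scenario_population(seed=9)
        with pytest.raises(ValueError, match="tc_scenario"):
            estimate_contribution(df)


class TestContributionUi:
    def test_zero_ses_collapse_to_deterministic_fraction(self):
        c91 = flat_curve(5.9, se=0.0)
        c11 = flat_curve(5.2, se=0.0)
        cns = flat_curve(5.4, se=0.0)
        est = contribution_ui(c91, c11, cns, 18, 89, n_draws=500, seed=1)
        assert est.ui_low == pytest.approx(est.point, rel=1e-12)
        assert est.ui_high == pytest.approx(est.point, rel=1e-12)
        assert est.point == pytest.approx(0.2 / 0.7, rel=1e-9)

    def test_same_seed_identical_ui(self):
        c91 = flat_curve(5.9, se=0.02)
        c11 = flat_curve(5.2, se=0.02)
        cns = flat_curve(5.4, se=0.02)
        a = contribution_ui(c91, c11, cns, 18, 89, n_draws=2000, seed=4)
        b = contribution_ui(c91, c11, cns, 18, 89, n_draws=2000, seed=4)
        assert (a.ui_low, a.ui_high) == (b.ui_low, b.ui_high)
        assert a.ui_low <= a.point <= a.ui_high

    def test_linked_narrower_than_independent_given_tight_gap(self):
        c91 = flat_curve(5.9, se=0.03)
        c11 = flat_curve(5.2, se=0.03)
        cns = flat_curve(5.4, se=0.03)
        gap = flat_curve(0.2, se=0.005, label="statin_gap")
        indep = contribution_ui(c91, c11, cns, 18, 89, n_draws=4000, seed=5)
        linked = contribution_ui(c91, c11, cns, 18, 89, n_draws=4000, seed=5,
                                 gap_curve=gap)
        assert (linked.ui_high - linked.ui_low) < (indep.ui_high - indep.ui_low)


class TestStratified:
    def test_table_and_trend_on_synthetic_population(self):
        df = scenario_population(seed=10, n=8000)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        table, z, p = stratified_contribution(scen, n_draws=300, seed=6)
        assert set(table["qimd"]) == {1, 2, 3, 4, 5}
        assert 0 <= p <= 1
        # prevalence has no QIMD gradient here, so no strong trend expected
        assert p > 1e-4

    def test_age_restriction_applies(self):
        df = scenario_population(seed=11, n=8000)
        scen = apply_no_statins_scenario(df, PooledEffect(0.257, 0.0))
        table, _, _ = stratified_contribution(
            scen, age_range=(18, 75), n_draws=200, seed=7
        )
        assert len(table) == 5  # runs despite sparse 76+ cells being unused


class TestSensitivity:
    def test_factor_one_is_identity(self, pooled):
        assert sensitivity_inflate(pooled, 1.0) == pooled

    def test_factor_ten_scales_se_only(self, pooled):
        out = sensitivity_inflate(pooled, 10.0)
        assert out.e_w == pooled.e_w
        assert out.se == pytest.approx(10 * pooled.se)
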