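import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from statincf import effects as fx


def effect_frame(rows):
    """rows: (statin, strength, tc_reduction, tc_se)"""
    return pd.DataFrame(
        [
            {
                "statin": s, "strength_mg": float(mg),
                "ldl_reduction": np.nan, "ldl_reduction_se": np.nan,
                "tc_reduction": e, "tc_reduction_se": se, "source": "measured",
            }
            for s, mg, e, se in rows
        ]
    )


def dispensing_frame(rows):
    """rows: (statin, strength, form, units)"""
    return pd.DataFrame(
        [
            {"statin": s, "strength_mg": float(mg), "form": f, "units": u}
            for s, mg, f, u in rows
        ],
        columns=["statin", "strength_mg", "form", "units"],
    )


class TestLdlToTc:
    @pytest.mark.parametrize(
        "ldl,se,factor,expected",
        [
            ((0.40), 0.02, 1.0, (0.40, 0.02)),
            ((0.40), 0.02, 0.75, (0.30, 0.015)),
        ],
    )
    def test_linear_map(self, ldl, se, factor, expected):
        assert fx.ldl_to_tc(ldl, se, factor) == pytest.approx(expected)

    def test_conversion_beyond_one_rejected(self):
        with pytest.raises(ValueError):
            fx.ldl_to_tc(0.90, 0.0, 1.2)


class TestNormalizeForms:
    def test_combination_becomes_plain_simvastatin(self):
        disp = dispensing_frame(
            [("simvastatin+ezetimibe", 20, "combination_with_ezetimibe", 100)]
        )
        out = fx.normalize_forms(disp)
        assert out.loc[0, "statin"] == "simvastatin"
        assert out.loc[0, "strength_mg"] == 20
        assert out.loc[0, "units"] == 100

    def test_liquid_keeps_statin_and_strength(self):
        disp = dispensing_frame([("atorvastatin", 20, "liquid", 50)])
        out = fx.normalize_forms(disp)
        assert out.loc[0, "statin"] == "atorvastatin"
        assert out.loc[0, "strength_mg"] == 20

    def test_empty_is_empty(self):
        out = fx.normalize_forms(dispensing_frame([]))
        assert len(out) == 0


def wls_normal_equations(x, y, w):
    """Brute-force weighted normal equations, the independent oracle."""
    X = np.column_stack([np.ones_like(x), x])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    return beta


class TestStrengthModel:
    def test_two_points_reproduced_exactly(self):
        eff = effect_frame(
            [("x", 10, 0.20, 0.01), ("x", 40, 0.30, 0.02)]
        )
        m = fx.fit_strength_model(eff)
        assert m.predict(10)[0] == pytest.approx(0.20, abs=1e-12)
        assert m.predict(40)[0] == pytest.approx(0.30, abs=1e-12)

    def test_collinear_points_zero_residuals(self):
        lnS = np.log([5, 20, 80])
        y = 0.1 + 0.05 * lnS
        eff = effect_frame(
            [("x", s, yi, se) for s, yi, se in zip([5, 20, 80], y, [0.01, 0.03, 0.02])]
        )
        m = fx.fit_strength_model(eff)
        for s, yi in zip([5, 20, 80], y):
            assert m.predict(s)[0] == pytest.approx(yi, abs=1e-10)

    @pytest.mark.parametrize("n_pts", [3, 4, 6])
    def test_matches_normal_equations_oracle(self, n_pts):
        rng = np.random.default_rng(n_pts)
        strengths = np.exp(rng.uniform(1, 4.5, n_pts))
        y = rng.uniform(0.1, 0.5, n_pts)
        se = rng.uniform(0.005, 0.05, n_pts)
        eff = effect_frame([("x", s, yi, si) for s, yi, si in zip(strengths, y, se)])
        m = fx.fit_strength_model(eff)
        b0, b1 = wls_normal_equations(np.log(strengths), y, 1 / se**2)
        assert m.intercept == pytest.approx(b0, rel=1e-10)
        assert m.slope == pytest.approx(b1, rel=1e-10)

    def test_single_strength_rejected(self):
        eff = effect_frame([("x", 10, 0.2, 0.01), ("x", 10, 0.21, 0.01)])
        with pytest.raises(ValueError, match="2 distinct"):
            fx.fit_strength_model(eff)


class TestExtrapolation:
    def test_geometric_mean_strength_gives_midpoint(self):
        # exact line through (ln 10, 0.20) and (ln 40, 0.30); 20 mg is the
        # geometric mean of 10 and 40, hence the midpoint in ln-strength
        eff = effect_frame([("x", 10, 0.20, 0.01), ("x", 40, 0.30, 0.01)])
        m = fx.fit_strength_model(eff)
        rec = fx.extrapolate_effect(m, 20)
        assert rec["tc_reduction"] == pytest.approx(0.25, abs=1e-12)
        assert rec["source"] == "extrapolated"

    def test_out_of_range_prediction_rejected(self):
        eff = effect_frame([("x", 10, 0.40, 0.01), ("x", 40, 0.90, 0.01)])
        m = fx.fit_strength_model(eff)
        with pytest.raises(ValueError, match="outside"):
            fx.extrapolate_effect(m, 640)

    def test_measured_strengths_never_overwritten(self):
        eff = effect_frame(
            [("x", 10, 0.20, 0.01), ("x", 40, 0.30, 0.01), ("x", 20, 0.33, 0.01)]
        )
        disp = dispensing_frame(
            [("x", 20, "solid", 10), ("x", 80, "solid", 5)]
        )
        full = fx.complete_effect_table(eff, disp)
        row20 = full[(full["strength_mg"] == 20)]
        assert row20["source"].tolist() == ["measured"]
        assert 80 in full["strength_mg"].tolist()


def gatz_smith_three_term_se(x, w):
    """Cochran weighted-mean SE in the original three-term form (oracle)."""
    x, w = np.asarray(x, float), np.asarray(w, float)
    n = len(x)
    wbar = w.mean()
    xbar = (w * x).sum() / w.sum()
    t1 = ((w * x - wbar * xbar) ** 2).sum()
    t2 = -2 * xbar * ((w - wbar) * (w * x - wbar * xbar)).sum()
    t3 = xbar**2 * ((w - wbar) ** 2).sum()
    return np.sqrt(n / ((n - 1) * w.sum() ** 2) * (t1 + t2 + t3))


class TestPooling:
    def test_single_record(self):
        eff = effect_frame([("x", 10, 0.30, 0.0)])
        disp = dispensing_frame([("x", 10, "solid", 1000)])
        pooled = fx.pool_effects(eff, disp)
        assert pooled.e_w == pytest.approx(0.30)

    def test_two_record_weighted_mean(self):
        eff = effect_frame([("x", 10, 0.20, 0.0), ("x", 40, 0.40, 0.0)])
        disp = dispensing_frame([("x", 10, "solid", 1), ("x", 40, "solid", 3)])
        assert fx.pool_effects(eff, disp).e_w == pytest.approx(0.35)

    def test_cochran_se_matches_three_term_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 0.5, 12)
        w = rng.uniform(1, 100, 12)
        assert fx.cochran_weighted_mean_se(x, w) == pytest.approx(
            gatz_smith_three_term_se(x, w), rel=1e-12
        )

    @given(st.floats(0.1, 100.0), st.integers(0, 10**6))
    def test_rescaling_units_leaves_pool_unchanged(self, scale, seed):
        rng = np.random.default_rng(seed)
        eff = effect_frame(
            [("x", s, e, 0.0) for s, e in zip([10, 20, 40], rng.uniform(0.1, 0.5, 3))]
        )
        units = rng.integers(1, 10**6, 3)
        disp = dispensing_frame(
            [("x", s, "solid", u) for s, u in zip([10, 20, 40], units)]
        )
        disp2 = disp.assign(units=disp["units"] * scale)
        p1, p2 = fx.pool_effects(eff, disp), fx.pool_effects(eff, disp2)
        assert p1.e_w == pytest.approx(p2.e_w, rel=1e-12)
        assert p1.se == pytest.approx(p2.se, rel=1e-9)

    def test_pool_within_effect_bounds_and_duplicate_merge(self):
        eff = effect_frame(
            [("x", 10, 0.15, 0.0), ("x", 20, 0.25, 0.0), ("y", 10, 0.45, 0.0)]
        )
        disp = dispensing_frame(
            [("x", 10, "solid", 5), ("x", 10, "solid", 7),
             ("x", 20, "solid", 3), ("y", 10, "solid", 2)]
        )
        merged = dispensing_frame(
            [("x", 10, "solid", 12), ("x", 20, "solid", 3), ("y", 10, "solid", 2)]
        )
        p1, p2 = fx.pool_effects(eff, disp), fx.pool_effects(eff, merged)
        assert p1.e_w == pytest.approx(p2.e_w, rel=1e-12)
        assert p1.se == pytest.approx(p2.se, rel=1e-12)
        assert 0.15 <= p1.e_w <= 0.45

    def test_orphan_dispensing_is_an_error(self):
        eff = effect_frame([("x", 10, 0.2, 0.0)])
        disp = dispensing_frame([("x", 10, "solid", 5), ("z", 40, "solid", 2)])
        with pytest.raises(ValueError, match="z"):
            fx.pool_effects(eff, disp)

    def test_zero_units_everywhere_is_an_error(self):
        eff = effect_frame([("x", 10, 0.2, 0.0)])
        disp = dispensing_frame([("x", 10, "solid", 0)])
        with pytest.raises(ValueError, match="units"):
            fx.pool_effects(eff, disp)


class TestBundledTables:
    def test_ci_to_se_conversion(self):
        eff = fx.load_bundled_effects()
        row = eff[(eff["statin"] == "atorvastatin") & (eff["strength_mg"] == 10)]
        assert row["ldl_reduction_se"].iloc[0] == pytest.approx(
            (0.39 - 0.35) / (2 * 1.959964), rel=1e-4
        )

    def test_units_conserved_through_normalisation(self):
        disp = fx.load_bundled_dispensing()
        before = disp["units"].sum()
        after = fx.normalize_forms(disp)["units"].sum()
        assert before == after
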