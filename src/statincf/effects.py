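"""Per-statin cholesterol effects and the dispensing-weighted population effect.

The population-level effect of statin use on total cholesterol (TC) among users,
``E_w``, is the dispensing-weighted mean of per-statin, per-strength proportional
TC reductions::

    E_w = sum_ij(M_ij * E_ij) / sum_ij(M_ij)

where ``E_ij`` is the proportional TC reduction of statin ``i`` at strength ``j``
and ``M_ij`` the number of dispensed units (one tablet, or 5 ml of liquid, is one
unit). Per-statin LDL reductions come from published meta-analyses and are
converted to TC reductions by a linear factor; strengths dispensed but not
trialled are filled in by an inverse-variance-weighted regression of the TC
reduction on log strength. The standard error of ``E_w`` uses Cochran's
frequency-weighted-mean formula in the Gatz & Smith (1995) formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

FORMS = ("solid", "liquid", "combination_with_ezetimibe")

#: Proportional TC reduction per proportional LDL reduction. Statins act almost
#: exclusively on LDL, so the absolute TC fall equals the absolute LDL fall and
#: the proportional conversion is the LDL share of TC at the meta-analysis
#: baseline (LDL 4.8 of TC ~6.9 mmol/L).
DEFAULT_LDL_TC_FACTOR = 0.70

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class PooledEffect:
    """Dispensing-weighted mean proportional TC reduction among statin users."""

    e_w: float
    se: float

    def __post_init__(self):
        if not 0.0 <= self.e_w < 1.0:
            raise ValueError(f"e_w must be in [0, 1), got {self.e_w}")
        if not np.isfinite(self.se) or self.se < 0:
            raise ValueError(f"se must be finite and >= 0, got {self.se}")

    @property
    def ci(self) -> tuple[float, float]:
        """Normal-theory 95% confidence interval."""
        return (self.e_w - _Z95 * self.se, self.e_w + _Z95 * self.se)


@dataclass
class StrengthModel:
    """WLS fit of TC reduction on ln(strength) for one statin."""

    statin: str
    intercept: float
    slope: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    equal_weights: bool = False

    def predict(self, strength_mg: float) -> tuple[float, float]:
        """Predicted TC reduction and its (prediction-mean) standard error."""
        x = np.array([1.0, np.log(strength_mg)])
        mean = float(x @ np.array([self.intercept, self.slope]))
        se = float(np.sqrt(x @ self.cov @ x))
        return mean, se


def ldl_to_tc(ldl_reduction: float, ldl_se: float, factor: float = DEFAULT_LDL_TC_FACTOR):
    """Convert a proportional LDL reduction (and SE) to a TC reduction linearly."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    tc = factor * ldl_reduction
    if not 0.0 < tc < 1.0:
        raise ValueError(f"converted TC reduction {tc:.3f} outside (0, 1)")
    return tc, factor * ldl_se


def read_effect_table(path, ldl_tc_factor: float = DEFAULT_LDL_TC_FACTOR) -> pd.DataFrame:
    """Read a per-statin LDL-effect CSV and attach TC-scale columns.

    Expected columns: statin, strength_mg, ldl_reduction, ldl_ci_low, ldl_ci_high.
    SEs are recovered from the 95% CI assuming approximate normality.
    """
    df = pd.read_csv(path, comment="#")
    needed = {"statin", "strength_mg", "ldl_reduction", "ldl_ci_low", "ldl_ci_high"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"effect table missing column(s): {sorted(missing)}")
    df = df.copy()
    df["ldl_reduction_se"] = (df["ldl_ci_high"] - df["ldl_ci_low"]) / (2 * _Z95)
    tc = df.apply(
        lambda r: ldl_to_tc(r["ldl_reduction"], r["ldl_reduction_se"], ldl_tc_factor),
        axis=1,
        result_type="expand",
    )
    df["tc_reduction"] = tc[0]
    df["tc_reduction_se"] = tc[1]
    df["source"] = "measured"
    return df[
        ["statin", "strength_mg", "ldl_reduction", "ldl_reduction_se",
         "tc_reduction", "tc_reduction_se", "source"]
    ]


def read_dispensing_table(path) -> pd.DataFrame:
    """Read a dispensing CSV with columns statin, strength_mg, form, units."""
    df = pd.read_csv(path, comment="#")
    needed = {"statin", "strength_mg", "form", "units"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"dispensing table missing column(s): {sorted(missing)}")
    bad_form = set(df["form"]) - set(FORMS)
    if bad_form:
        raise ValueError(f"unknown form(s): {sorted(bad_form)}")
    if (df["units"] < 0).any() or (df["strength_mg"] <= 0).any():
        raise ValueError("units must be >= 0 and strength_mg > 0")
    return df[["statin", "strength_mg", "form", "units"]].copy()


def load_bundled_effects(ldl_tc_factor: float = DEFAULT_LDL_TC_FACTOR) -> pd.DataFrame:
    """The packaged meta-analytic LDL effect table, converted to TC scale."""
    ref = resources.files("statincf.data") / "ldl_effects.csv"
    with resources.as_file(ref) as p:
        return read_effect_table(p, ldl_tc_factor)


def load_bundled_dispensing() -> pd.DataFrame:
    """The packaged synthetic reconstruction of England 2011+2012 dispensing units."""
    ref = resources.files("statincf.data") / "dispensing_england_2011_2012_synthetic.csv"
    with resources.as_file(ref) as p:
        return read_dispensing_table(p)


def normalize_forms(dispensings: pd.DataFrame) -> pd.DataFrame:
    """Apply the form-equivalence rules, conserving units.

    Combination products of simvastatin with ezetimibe count as plain
    simvastatin of the same strength; liquid forms keep their statin and
    strength (solid and liquid are treated as equally effective).
    """
    out = dispensings.copy()
    combo = out["form"] == "combination_with_ezetimibe"
    out.loc[combo, "statin"] = "simvastatin"
    out.loc[combo, "form"] = "solid"
    return out


def fit_strength_model(effects: pd.DataFrame) -> StrengthModel:
    """Inverse-variance-weighted regression of TC reduction on ln(strength).

    Requires at least two distinct measured strengths for a single statin.
    If any SE is zero the fit falls back to equal weights (logged).
    """
    statins = set(effects["statin"])
    if len(statins) != 1:
        raise ValueError(f"expected one statin, got {sorted(statins)}")
    (statin,) = statins
    measured = effects[effects["source"] == "measured"]
    if measured["strength_mg"].nunique() < 2:
        raise ValueError(f"need >= 2 distinct measured strengths for {statin}")
    x = np.log(measured["strength_mg"].to_numpy(float))
    y = measured["tc_reduction"].to_numpy(float)
    se = measured["tc_reduction_se"].to_numpy(float)
    equal = bool((se == 0).any())
    if equal:
        logger.warning("%s: zero SE in effect table; using equal WLS weights", statin)
        w = np.ones_like(y)
    else:
        w = 1.0 / se**2
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    params = np.asarray(fit.params)
    # coefficient covariance with an explicit scale so a saturated 2-point fit
    # gets cov 0 instead of statsmodels' 0/0
    resid = y - X @ params
    df_resid = len(y) - 2
    scale = float((w * resid**2).sum() / df_resid) if df_resid > 0 else 0.0
    xtwx_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    return StrengthModel(
        statin=statin,
        intercept=float(params[0]),
        slope=float(params[1]),
        cov=scale * xtwx_inv,
        equal_weights=equal,
    )


def extrapolate_effect(model: StrengthModel, strength_mg: float) -> pd.Series:
    """Predict the effect of an untrialled strength from the log-strength model."""
    mean, se = model.predict(strength_mg)
    if not 0.0 < mean < 1.0:
        raise ValueError(
            f"extrapolated TC reduction {mean:.3f} for {model.statin} "
            f"{strength_mg} mg outside (0, 1)"
        )
    return pd.Series(
        {
            "statin": model.statin,
            "strength_mg": float(strength_mg),
            "ldl_reduction": np.nan,
            "ldl_reduction_se": np.nan,
            "tc_reduction": mean,
            "tc_reduction_se": se,
            "source": "extrapolated",
        }
    )


def complete_effect_table(effects: pd.DataFrame, dispensings: pd.DataFrame) -> pd.DataFrame:
    """Extend the measured effect table to every dispensed (statin, strength).

    Measured strengths always keep their measured value; extrapolation only
    fills gaps. Dispensing should already be form-normalised.
    """
    needed = dispensings[["statin", "strength_mg"]].drop_duplicates()
    new_rows: list[dict] = []
    models: dict[str, StrengthModel] = {}
    for _, rec in needed.iterrows():
        statin, strength = rec["statin"], float(rec["strength_mg"])
        have = effects[
            (effects["statin"] == statin) & (effects["strength_mg"] == strength)
        ]
        if len(have):
            continue
        sub = effects[effects["statin"] == statin]
        if len(sub) == 0:
            raise ValueError(f"no measured effects at all for statin {statin!r}")
        if statin not in models:
            models[statin] = fit_strength_model(sub)
        new_rows.append(extrapolate_effect(models[statin], strength).to_dict())
    out = effects.copy()
    if new_rows:
        out = pd.concat([effects, pd.DataFrame(new_rows)], ignore_index=True)
    out["strength_mg"] = out["strength_mg"].astype(float)
    for col in ("ldl_reduction", "ldl_reduction_se", "tc_reduction", "tc_reduction_se"):
        out[col] = out[col].astype(float)
    return out


def cochran_weighted_mean_se(values: np.ndarray, weights: np.ndarray) -> float:
    """Cochran's SE of a frequency-weighted mean (Gatz & Smith 1995 form).

    The bracketed three-term expression in Gatz & Smith collapses algebraically
    to ``sum(w_i^2 (x_i - xbar_w)^2)``, which is what is computed here.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    n = len(values)
    if n < 2:
        return 0.0
    wsum = weights.sum()
    xbar = float((weights * values).sum() / wsum)
    s2 = (weights**2 * (values - xbar) ** 2).sum()
    return float(np.sqrt(n / (n - 1.0) * s2) / wsum)


def pool_effects(effects: pd.DataFrame, dispensings: pd.DataFrame) -> PooledEffect:
    """Dispensing-weighted pooled TC reduction ``E_w`` with Cochran SE.

    ``dispensings`` should be form-normalised; duplicate (statin, strength)
    cells are merged by summing units before pooling, and zero-unit cells are
    dropped. Every dispensed cell must have a matching effect record.
    """
    disp = (
        dispensings.groupby(["statin", "strength_mg"], as_index=False)["units"].sum()
    )
    disp = disp[disp["units"] > 0]
    if len(disp) == 0 or disp["units"].sum() <= 0:
        raise ValueError("no dispensing units to weight by")
    merged = disp.merge(
        effects[["statin", "strength_mg", "tc_reduction"]],
        on=["statin", "strength_mg"],
        how="left",
        validate="one_to_one",
    )
    orphans = merged[merged["tc_reduction"].isna()]
    if len(orphans):
        pairs = [
            f"{r.statin} {r.strength_mg:g} mg" for r in orphans.itertuples()
        ]
        raise ValueError(f"dispensing cells without an effect record: {pairs}")
    w = merged["units"].to_numpy(float)
    e = merged["tc_reduction"].to_numpy(float)
    e_w = float((w * e).sum() / w.sum())
    se = cochran_weighted_mean_se(e, w)
    return PooledEffect(e_w=e_w, se=se)


def pooled_effect_from_tables(
    effects_path=None,
    dispensing_path=None,
    ldl_tc_factor: float = DEFAULT_LDL_TC_FACTOR,
) -> PooledEffect:
    """Convenience end-to-end pooling: read, normalise, complete, pool.

    With no paths, uses the bundled meta-analysis effect table and the bundled
    synthetic England 2011+2012 dispensing reconstruction.
    """
    effects = (
        read_effect_table(effects_path, ldl_tc_factor)
        if effects_path is not None
        else load_bundled_effects(ldl_tc_factor)
    )
    disp = (
        read_dispensing_table(dispensing_path)
        if dispensing_path is not None
        else load_bundled_dispensing()
    )
    disp = normalize_forms(disp)
    effects = complete_effect_table(effects, disp)
    return pool_effects(effects, disp)
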