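"""End-to-end orchestration: load/simulate -> adjust -> pool -> scenario ->
curves -> contribution -> gradients -> sensitivity, with a reproducible
manifest.

All randomness flows from one master seed through named sub-streams (one per
stage), so the stratified analysis never perturbs the overall run's draws and
any stage can be replayed independently.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import counterfactual, effects, surveystats, survey_io
from .contribution import (
    DEFAULT_AGE_RANGE,
    STRATIFIED_AGE_RANGE,
    estimate_contribution,
    sensitivity_inflate,
    stratified_contribution,
)
from .survey_io import PERIOD_1991, PERIOD_2011
from .synthetic import SyntheticConfig, generate_population

_STAGES = ("simulate", "scenario", "contribution", "stratified", "sensitivity")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Constants of a full pipeline run."""

    participants_path: str | None = None
    schema: dict | None = None
    effects_path: str | None = None
    dispensing_path: str | None = None
    synthetic: SyntheticConfig | None = None
    ldl_tc_factor: float = effects.DEFAULT_LDL_TC_FACTOR
    equipment_offset: float = 0.1
    user_draws: int = 1000
    age_draws: int = 10_000
    seed: int = 0
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE
    stratified_age_range: tuple[int, int] = STRATIFIED_AGE_RANGE
    sensitivity_factor: float = 10.0
    ui_mode: str = "linked"
    output_dir: str | None = None

    def validate(self):
        if self.user_draws < 1 or self.age_draws < 1:
            raise ValueError("draw counts must be positive")
        for lo, hi in (self.age_range, self.stratified_age_range):
            if lo >= hi:
                raise ValueError("age_lo must be < age_hi")
        if self.participants_path is None and self.synthetic is None:
            raise ValueError("either participants_path or synthetic must be given")
        return self


def population_mean_tc(df: pd.DataFrame, period: str, col: str = "tc_mmol"):
    """Design-based mean cholesterol of one period's sample."""
    sub = df[(df["period"] == period) & df[col].notna()]
    return surveystats.weighted_mean(
        sub[col], sub["weight"], sub["psu"], sub["stratum"]
    )


def statin_prevalence_estimate(df: pd.DataFrame, period: str = PERIOD_2011):
    """Design-based statin-use prevalence with an incomplete-beta CI."""
    sub = df[df["period"] == period]
    return surveystats.design_proportion_ci(
        sub["statin_user"].astype(float), sub["weight"], sub["psu"], sub["stratum"]
    )


def consistency_check_units(
    participants: pd.DataFrame,
    observed_units: float,
    population_total: float,
    days: int = 365,
    doses_per_day: float = 1.0,
) -> tuple[float, float, float]:
    """Compare dispensing totals against survey-implied consumption.

    Expected units = weighted statin-use prevalence x adult population x days
    x doses per day; the relative gap is (observed - expected) / observed.
    """
    if observed_units <= 0:
        raise ValueError("observed_units must be positive")
    prev = statin_prevalence_estimate(participants).p
    expected = prev * population_total * days * doses_per_day
    gap = (observed_units - expected) / observed_units
    return expected, observed_units, gap


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return (and optionally write) the report bundle."""
    config.validate()
    t0 = time.time()
    report: dict = {"config": _jsonable(asdict(config)), "stages": {}}
    timings = {}

    def _stage(name):
        timings[name] = time.time()

    # load / simulate
    _stage("load")
    if config.participants_path is not None:
        df = survey_io.read_participants(config.participants_path, config.schema)
    else:
        df, _truth = generate_population(
            config.synthetic, seed=stage_seed(config.seed, "simulate")
        )
    df = survey_io.adjust_equipment_offset(df, config.equipment_offset)
    kept, missing_report = survey_io.exclude_missing(df, ("tc_mmol",))
    report["stages"]["load"] = {
        "n_total": int(len(df)),
        "n_with_tc": int(len(kept)),
        "excluded": missing_report,
    }

    # pooled effect
    pooled = effects.pooled_effect_from_tables(
        config.effects_path, config.dispensing_path, config.ldl_tc_factor
    )
    report["stages"]["pooled_effect"] = {
        "e_w": pooled.e_w, "se": pooled.se, "ci": list(pooled.ci)
    }

    # prevalence and gradients
    prev = statin_prevalence_estimate(df)
    report["stages"]["prevalence_2011"] = {
        "p": prev.p, "ci": [prev.ci_low, prev.ci_high], "n_eff": prev.n_effective
    }
    d11 = kept[kept["period"] == PERIOD_2011]
    d91 = kept[kept["period"] == PERIOD_1991]
    grad = {}
    grad["tc_qimd_2011"] = asdict(
        surveystats.fit_gradient_slope(
            d11, "tc_mmol", "qimd", "gaussian", adjust=("age", "sex")
        )
    )
    grad["tc_class_1991"] = asdict(
        surveystats.fit_gradient_slope(
            d91, "tc_mmol", "social_class", "gaussian", adjust=("age", "sex")
        )
    )
    full11 = df[df["period"] == PERIOD_2011]
    grad["statin_qimd_2011"] = asdict(
        surveystats.fit_gradient_slope(
            full11, "statin_user", "qimd", "binomial", adjust=("age", "sex")
        )
    )
    report["stages"]["gradients"] = grad

    # counterfactual scenario
    scen = counterfactual.apply_no_statins_scenario(
        kept, pooled, config.user_draws, stage_seed(config.seed, "scenario")
    )
    report["stages"]["mean_tc"] = {
        "observed_1991": asdict(population_mean_tc(scen, PERIOD_1991)),
        "observed_2011": asdict(population_mean_tc(scen, PERIOD_2011)),
        "no_statins_2011": asdict(
            population_mean_tc(scen, PERIOD_2011, "tc_scenario")
        ),
    }

    # contribution: overall, per sex, stratified
    contrib = {}
    c_seed = stage_seed(config.seed, "contribution")
    overall = estimate_contribution(
        scen, age_range=config.age_range, n_draws=config.age_draws,
        seed=c_seed, mode=config.ui_mode,
    )
    contrib["overall"] = asdict(overall)
    for sex in ("male", "female"):
        contrib[sex] = asdict(
            estimate_contribution(
                scen, sexes=(sex,), age_range=config.age_range,
                n_draws=config.age_draws, seed=c_seed + (1 if sex == "male" else 2),
                mode=config.ui_mode,
            )
        )
    strat_table, trend_z, trend_p = stratified_contribution(
        scen, age_range=config.stratified_age_range, n_draws=config.age_draws,
        seed=stage_seed(config.seed, "stratified"), mode=config.ui_mode,
    )
    contrib["by_qimd"] = strat_table.to_dict(orient="records")
    contrib["qimd_trend"] = {"z": trend_z, "p": trend_p}
    report["stages"]["contribution"] = contrib

    # sensitivity: inflate se(E_w) and re-run the scenario + overall estimate
    inflated = sensitivity_inflate(pooled, config.sensitivity_factor)
    scen_s = counterfactual.apply_no_statins_scenario(
        kept, inflated, config.user_draws, stage_seed(config.seed, "sensitivity")
    )
    sens = estimate_contribution(
        scen_s, age_range=config.age_range, n_draws=config.age_draws,
        seed=c_seed, mode=config.ui_mode,
    )
    report["stages"]["sensitivity"] = {
        "factor": config.sensitivity_factor,
        "contribution": asdict(sens),
        "mean_tc_no_statins": asdict(
            population_mean_tc(scen_s, PERIOD_2011, "tc_scenario")
        ),
        "shift_vs_main": sens.point - overall.point,
    }

    report["manifest"] = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "config_hash": hashlib.sha256(
            json.dumps(report["config"], sort_keys=True, default=str).encode()
        ).hexdigest(),
        "elapsed_s": round(time.time() - t0, 3),
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        strat_table.to_csv(out / "contribution_by_qimd.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
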