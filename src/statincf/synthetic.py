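"""Synthetic two-period survey microdata with known ground truth.

Emulates the structure of Health Survey for England style microdata for an
unweighted early-1990s baseline and a weighted 2011-12-like period: stratified
cluster design, per-(age, sex) cholesterol distributions with a secular
downward trend, statin-use prevalence with age, sex and deprivation (QIMD)
gradients, a known multiplicative statin effect on users' cholesterol, survey
weights, the post-April-2010 analyser offset, and missing cholesterol
measurements. Default parameters are calibrated to published HSE 1991-2012
summary statistics (age-group mean cholesterol by sex and period, statin-use
prevalence ~13% with a deprivation gradient in ages 35+).

The generator writes the true counterfactual cholesterol and true user flag to
a separate truth table so the analysis pipeline cannot consume them, and
:func:`ground_truth_contribution` computes the generative statin share of the
cholesterol decline analytically (no sampling), for parameter-recovery
studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contribution import DEFAULT_AGE_RANGE, integration_weights
from .survey_io import OFFSET_ATTR, PERIOD_1991, PERIOD_2011

AGE_MIN, AGE_MAX = 18, 95

_AGE_GROUPS = ((18, 34), (35, 54), (55, 95))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Generative model parameters; defaults emulate the England 1991/2011 setting."""

    n_per_period: int = 20_000
    #: P(male)
    sex_ratio: float = 0.46
    #: P(age group) per period, groups 18-34 / 35-54 / 55-95
    age_group_probs: dict = field(
        default_factory=lambda: {
            PERIOD_1991: (0.31, 0.34, 0.35),
            PERIOD_2011: (0.28, 0.36, 0.36),
        }
    )
    #: QIMD quintile probabilities (2011-like period), 1 = most affluent
    qimd_distribution: tuple = (0.223, 0.221, 0.209, 0.182, 0.165)
    #: social class I..V + Other probabilities (baseline period)
    social_class_distribution: tuple = (0.041, 0.250, 0.231, 0.209, 0.164, 0.074, 0.031)
    #: ages anchoring the piecewise-linear mean-cholesterol age profiles
    tc_anchor_ages: tuple = (26, 45, 67)
    #: baseline (1991-like) mean total cholesterol at the anchor ages, mmol/L
    tc_baseline_mean: dict = field(
        default_factory=lambda: {
            "male": (5.20, 5.97, 6.10),
            "female": (5.06, 5.70, 6.84),
        }
    )
    #: within-stratum SD of total cholesterol, mmol/L
    tc_sd: float = 1.05
    #: additive change in counterfactual mean cholesterol at the anchor ages
    #: between the periods (diet and other non-statin drivers)
    secular_trend: dict = field(
        default_factory=lambda: {
            "male": (-0.45, -0.37, -0.54),
            "female": (-0.44, -0.39, -0.80),
        }
    )
    #: additive per-QIMD shift of counterfactual cholesterol in the recent
    #: period (default none: the observed gradient emerges from statin use)
    ses_gradient_2011: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    #: statin-use base log-odds per (sex, age group) in the recent period
    statin_base_logit: dict = field(
        default_factory=lambda: {
            "male": (-5.8, -2.59, -0.49),
            "female": (-5.8, -3.18, -1.045),
        }
    )
    #: log-odds increase per QIMD quintile (use rises with deprivation)
    statin_qimd_slope: float = 0.12
    #: multiplicative proportional reduction of users' total cholesterol
    true_effect: float = 0.257
    #: lognormal sigma of the recent-period survey weights (mean kept at 1)
    weight_sigma: float = 0.35
    n_strata: int = 10
    psus_per_stratum: int = 40
    #: SD of the PSU-level cholesterol intercept (induces a design effect)
    psu_sd: float = 0.06
    missing_tc_rate: float = 0.29
    #: analyser offset added to recorded recent-period cholesterol (the
    #: pipeline's equipment adjustment must remove it)
    equipment_offset: float = 0.1
    #: optional confounding by indication: log-odds of statin use per mmol/L
    #: of counterfactual cholesterol above the (age, sex) mean; default off
    confounding_logit_per_mmol: float = 0.0
    seed: int = 0

    def validate(self):
        if self.n_per_period < 1:
            raise ValueError("n_per_period must be positive")
        if not 0.0 <= self.true_effect < 1.0:
            raise ValueError("true_effect must be in [0, 1)")
        if abs(sum(self.qimd_distribution) - 1.0) > 1e-9:
            raise ValueError("qimd_distribution must sum to 1")
        for rate in (self.missing_tc_rate, self.sex_ratio):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.tc_sd <= 0 or self.psu_sd < 0 or self.weight_sigma < 0:
            raise ValueError("scale parameters must be non-negative (tc_sd > 0)")
        for probs in self.age_group_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("age_group_probs must sum to 1")
        return self

    # -- deterministic pieces of the generative model ------------------------

    def age_weights(self, period: str) -> np.ndarray:
        """P(age) over 18..95: group probabilities, decaying within 55+."""
        probs = self.age_group_probs[period]
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        w = np.zeros(len(ages), float)
        for (lo, hi), p in zip(_AGE_GROUPS, probs):
            mask = (ages >= lo) & (ages <= hi)
            within = np.ones(mask.sum())
            if lo == 55:  # old ages thin out linearly
                within = np.linspace(1.0, 0.05, mask.sum())
            w[mask] = p * within / within.sum()
        return w / w.sum()

    def tc_mean_baseline(self, ages, sex: str) -> np.ndarray:
        return np.interp(ages, self.tc_anchor_ages, self.tc_baseline_mean[sex])

    def tc_mean_counterfactual(self, ages, sex: str) -> np.ndarray:
        """Recent-period mean cholesterol had nobody used statins (before any
        QIMD shift)."""
        trend = np.interp(ages, self.tc_anchor_ages, self.secular_trend[sex])
        return self.tc_mean_baseline(ages, sex) + trend

    def statin_prevalence(self, ages, sex: str, qimd) -> np.ndarray:
        group = np.digitize(np.asarray(ages), [35, 55])  # 0,1,2
        base = np.asarray(self.statin_base_logit[sex])[group]
        return _sigmoid(base + self.statin_qimd_slope * (np.asarray(qimd) - 3.0))


DEFAULT_CONFIG = SyntheticConfig()


def generate_population(
    config: SyntheticConfig = DEFAULT_CONFIG, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the two-period participant table plus a ground-truth sidecar.

    Returns ``(participants, truth)``: the participant table in the canonical
    schema (recorded cholesterol includes the analyser offset for the recent
    period), and a truth table with ``id``, ``tc_counterfactual`` and
    ``is_true_user``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames, truths = [], []
    for period in (PERIOD_1991, PERIOD_2011):
        n = config.n_per_period
        ages = rng.choice(
            np.arange(AGE_MIN, AGE_MAX + 1), size=n, p=config.age_weights(period)
        )
        male = rng.random(n) < config.sex_ratio
        sex = np.where(male, "male", "female")

        if period == PERIOD_2011:
            qimd = rng.choice(np.arange(1, 6), size=n, p=config.qimd_distribution)
            social = np.full(n, None, dtype=object)
        else:
            qimd = np.full(n, np.nan)
            classes = np.array(["I", "II", "IIIN", "IIIM", "IV", "V", "Other"])
            social = rng.choice(
                classes, size=n, p=config.social_class_distribution
            ).astype(object)

        stratum_i = rng.integers(0, config.n_strata, size=n)
        psu_i = rng.integers(0, config.psus_per_stratum, size=n)
        psu_effects = rng.normal(
            0.0, config.psu_sd, size=(config.n_strata, config.psus_per_stratum)
        )

        mean = np.empty(n)
        for s in ("male", "female"):
            m = sex == s
            if period == PERIOD_1991:
                mean[m] = config.tc_mean_baseline(ages[m], s)
            else:
                mean[m] = config.tc_mean_counterfactual(ages[m], s)
        if period == PERIOD_2011:
            mean += np.asarray(config.ses_gradient_2011)[qimd.astype(int) - 1]
        mean += psu_effects[stratum_i, psu_i]
        tc_cf = rng.normal(mean, config.tc_sd)
        tc_cf = np.maximum(tc_cf, 0.5)  # physiological floor

        if period == PERIOD_2011:
            logit_shift = config.confounding_logit_per_mmol * (tc_cf - mean)
            group = np.digitize(ages, [35, 55])
            base = np.where(
                male,
                np.asarray(config.statin_base_logit["male"])[group],
                np.asarray(config.statin_base_logit["female"])[group],
            )
            p_use = _sigmoid(
                base + config.statin_qimd_slope * (qimd - 3.0) + logit_shift
            )
            user = rng.random(n) < p_use
        else:
            user = np.zeros(n, dtype=bool)

        tc_obs = np.where(user, tc_cf * (1.0 - config.true_effect), tc_cf)
        post_2010 = period == PERIOD_2011
        tc_recorded = tc_obs + (config.equipment_offset if post_2010 else 0.0)
        missing = rng.random(n) < config.missing_tc_rate
        tc_recorded = np.where(missing, np.nan, tc_recorded)

        if period == PERIOD_2011 and config.weight_sigma > 0:
            weight = rng.lognormal(
                -0.5 * config.weight_sigma**2, config.weight_sigma, size=n
            )
        else:
            weight = np.ones(n)

        ids = np.array([f"{period[:4]}-{i:06d}" for i in range(n)], dtype=object)
        frames.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "age": ages.astype(int),
                    "sex": sex,
                    "period": period,
                    "qimd": qimd,
                    "social_class": social,
                    "weight": weight,
                    "psu": [f"s{h}p{j}" for h, j in zip(stratum_i, psu_i)],
                    "stratum": [f"s{h}" for h in stratum_i],
                    "statin_user": user,
                    "tc_mmol": tc_recorded,
                    "measured_post_2010_04": post_2010,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {"id": ids, "tc_counterfactual": tc_cf, "is_true_user": user}
            )
        )
    participants = pd.concat(frames, ignore_index=True)
    participants.attrs[OFFSET_ATTR] = False
    return participants, pd.concat(truths, ignore_index=True)


# -- analytic expectations ---------------------------------------------------


def _expected_curves(config: SyntheticConfig, sex: str, age_range):
    """Expected per-age means of the three curves, with the top bin pooled."""
    lo, hi = age_range
    ages_fine = np.arange(lo, AGE_MAX + 1)
    m91 = config.tc_mean_baseline(ages_fine, sex)
    pi_q = np.asarray(config.qimd_distribution)
    g_q = np.asarray(config.ses_gradient_2011)
    m_cf_base = config.tc_mean_counterfactual(ages_fine, sex)
    # mix over QIMD
    m_cf = np.zeros(len(ages_fine))
    m_obs = np.zeros(len(ages_fine))
    for q in range(1, 6):
        prev = config.statin_prevalence(ages_fine, sex, q)
        mq = m_cf_base + g_q[q - 1]
        m_cf += pi_q[q - 1] * mq
        m_obs += pi_q[q - 1] * mq * (1.0 - prev * config.true_effect)

    def pool(values, period):
        w_age = config.age_weights(period)
        idx = np.arange(AGE_MIN, AGE_MAX + 1)
        out = values[: hi - lo].tolist()
        top = (idx >= hi) & (idx <= AGE_MAX)
        wt = w_age[top]
        out.append(float((values[hi - lo :] * wt).sum() / wt.sum()))
        return np.asarray(out)

    return pool(m91, PERIOD_1991), pool(m_obs, PERIOD_2011), pool(m_cf, PERIOD_2011)


def ground_truth_contribution(
    config: SyntheticConfig = DEFAULT_CONFIG,
    *,
    sexes=("male", "female"),
    age_range=DEFAULT_AGE_RANGE,
) -> float:
    """Expected (area B) / (area A) under the generative model, no sampling.

    Uses the same natural-spline area statistic as the pipeline, applied to
    the exact expected per-age curves (with the top age bin pooled by the
    period's age distribution). Valid when the confounding knob is off.
    """
    config.validate()
    lo, hi = age_range
    w = integration_weights(np.arange(lo, hi + 1), lo, hi)
    area_a = area_b = 0.0
    for sex in sexes:
        m91, m_obs, m_cf = _expected_curves(config, sex, age_range)
        area_a += float(w @ (m91 - m_obs))
        area_b += float(w @ (m_cf - m_obs))
    if area_a == 0:
        raise ValueError("expected area A is zero")
    return area_b / area_a


def expected_prevalence(
    config: SyntheticConfig = DEFAULT_CONFIG, period: str = PERIOD_2011
) -> float:
    """Marginal expected statin-use prevalence in the recent period."""
    if period != PERIOD_2011:
        return 0.0
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    w_age = config.age_weights(PERIOD_2011)
    pi_q = np.asarray(config.qimd_distribution)
    total = 0.0
    for sex, p_sex in (("male", config.sex_ratio), ("female", 1 - config.sex_ratio)):
        for q in range(1, 6):
            total += p_sex * float(
                (w_age * pi_q[q - 1] * config.statin_prevalence(ages, sex, q)).sum()
            )
    return total


def config_with(**overrides) -> SyntheticConfig:
    """A default config with selected fields replaced."""
    return replace(SyntheticConfig(), **overrides).validate()
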