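"""Age curves, spline areas and the statin contribution statistic.

The decline in population mean total cholesterol between the baseline and
recent survey periods is summarised per sex by three age curves: observed
baseline (1991-92), observed recent (2011-12), and the 'no statins' scenario.
With natural cubic splines through the per-age means,

* area A = integral of (baseline - recent)     : the full observed decline,
* area B = integral of (no-statins - recent)   : the statin-attributable part,

and B / A is the contribution of statins to the decline. Uncertainty intervals
come from Monte Carlo perturbation of the per-age means by their design-based
standard errors. Because spline interpolation and integration are linear in
the per-age means, each curve's integral is a fixed weight vector dotted with
its means, which makes the Monte Carlo exact and fast.

Two propagation modes are provided. The default, ``mode="linked"``, perturbs
the baseline curve independently and the (recent, statin-gap) pair jointly —
the gap curve (no-statins minus recent) is estimated with its own design SE
and its per-age sampling covariance with the recent curve, both from the same
respondents — then reconstructs the no-statins curve as recent + gap. This
respects the sampling correlation structure of curves computed from one
sample: the no-statins and recent curves are near-perfectly correlated, and
the gap is negatively correlated with the recent curve (a chance excess of
statin users lowers the observed mean while raising the gap).
``mode="independent"`` perturbs all three curves independently; it is much
more conservative for area B (it can produce artefactual negative lower
bounds) but is retained for comparability with analyses that treated the
curves as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .effects import PooledEffect
from .survey_io import PERIOD_1991, PERIOD_2011
from .surveystats import cochran_armitage, weighted_mean, weighted_mean_pair

logger = logging.getLogger(__name__)

DEFAULT_AGE_RANGE = (18, 89)
STRATIFIED_AGE_RANGE = (18, 75)  # QIMD cells above 75 are too sparse
DEFAULT_UI_DRAWS = 10_000


@dataclass
class AgeCurve:
    """Per-single-year-of-age design-based mean cholesterol for one scenario."""

    label: str
    ages: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray
    sex: str | None = None
    stratum: str | None = None
    sparse_ages: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, int)
        self.mean = np.asarray(self.mean, float)
        self.se = np.asarray(self.se, float)
        self.n = np.asarray(self.n, int)
        if not np.all(np.diff(self.ages) == 1):
            raise ValueError("ages must be contiguous increasing integers")

    def covers(self, lo: int, hi: int) -> bool:
        return self.ages[0] <= lo and self.ages[-1] >= hi


@dataclass(frozen=True)
class ContributionEstimate:
    """Area-ratio point estimate with Monte Carlo 95% uncertainty interval."""

    point: float
    ui_low: float
    ui_high: float
    mc_mean: float
    area_a: float
    area_b: float
    n_draws: int
    seed: int | None


def build_age_curve(
    participants: pd.DataFrame,
    tc_col: str = "tc_mmol",
    *,
    label: str = "",
    sex: str | None = None,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    min_n: int = 2,
    single_psu: str = "center",
) -> AgeCurve:
    """Design-aware mean cholesterol per single year of age.

    Participants older than the top age are pooled into the top bin (the
    survey has very few respondents above 89). Ages with fewer than ``min_n``
    respondents are flagged and borrow the SE of the nearest adequate age.
    """
    lo, hi = age_range
    df = participants
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df[df[tc_col].notna() & (df["age"] >= lo)]
    if len(df) == 0:
        raise ValueError("no participants in the requested age range")
    agebin = np.minimum(df["age"].to_numpy(int), hi)
    ages = np.arange(lo, hi + 1)
    means = np.full(len(ages), np.nan)
    ses = np.full(len(ages), np.nan)
    ns = np.zeros(len(ages), int)
    sparse: list[int] = []
    for k, a in enumerate(ages):
        sub = df[agebin == a]
        if len(sub) == 0:
            raise ValueError(f"no participants at age {a}")
        est = weighted_mean(
            sub[tc_col],
            sub["weight"],
            sub["psu"],
            sub["stratum"],
            single_psu=single_psu,
        )
        means[k], ses[k], ns[k] = est.mean, est.se, est.n
        if est.n < min_n:
            sparse.append(int(a))
    # sparse ages borrow the SE of the nearest adequately sized age
    ok = ns >= min_n
    if sparse and ok.any():
        idx_ok = np.flatnonzero(ok)
        for k in np.flatnonzero(~ok):
            ses[k] = ses[idx_ok[np.argmin(np.abs(idx_ok - k))]]
    return AgeCurve(
        label=label, ages=ages, mean=means, se=ses, n=ns, sex=sex, sparse_ages=sparse
    )


def build_age_curve_pair(
    participants: pd.DataFrame,
    col_1: str,
    col_2: str,
    *,
    labels: tuple[str, str] = ("", ""),
    sex: str | None = None,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    min_n: int = 2,
    single_psu: str = "center",
) -> tuple[AgeCurve, AgeCurve, np.ndarray]:
    """Two age curves from the same respondents plus their per-age sampling
    correlation (design-based, Taylor-linearised)."""
    lo, hi = age_range
    df = participants
    if sex is not None:
        df = df[df["sex"] == sex]
    df = df[df[col_1].notna() & df[col_2].notna() & (df["age"] >= lo)]
    if len(df) == 0:
        raise ValueError("no participants in the requested age range")
    agebin = np.minimum(df["age"].to_numpy(int), hi)
    ages = np.arange(lo, hi + 1)
    k = len(ages)
    means = np.full((k, 2), np.nan)
    ses = np.full((k, 2), np.nan)
    rho = np.zeros(k)
    ns = np.zeros(k, int)
    sparse: list[int] = []
    for i, a in enumerate(ages):
        sub = df[agebin == a]
        if len(sub) == 0:
            raise ValueError(f"no participants at age {a}")
        e1, e2, cov = weighted_mean_pair(
            sub[col_1], sub[col_2], sub["weight"], sub["psu"], sub["stratum"],
            single_psu=single_psu,
        )
        means[i] = e1.mean, e2.mean
        ses[i] = e1.se, e2.se
        if e1.se > 0 and e2.se > 0:
            rho[i] = np.clip(cov / (e1.se * e2.se), -1.0, 1.0)
        ns[i] = e1.n
        if e1.n < min_n:
            sparse.append(int(a))
    ok = ns >= min_n
    if sparse and ok.any():
        idx_ok = np.flatnonzero(ok)
        for i in np.flatnonzero(~ok):
            j = idx_ok[np.argmin(np.abs(idx_ok - i))]
            ses[i] = ses[j]
            rho[i] = rho[j]
    curves = tuple(
        AgeCurve(
            label=labels[j], ages=ages, mean=means[:, j], se=ses[:, j], n=ns,
            sex=sex, sparse_ages=sparse,
        )
        for j in range(2)
    )
    return curves[0], curves[1], rho


def integration_weights(ages: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Weights ``w`` with ``w @ y`` = integral over [lo, hi] of the natural
    cubic spline through (ages, y). Exact because spline fitting and
    integration are linear in ``y``."""
    ages = np.asarray(ages, float)
    if lo < ages[0] or hi > ages[-1]:
        raise ValueError("integration range outside the curve's age grid")
    basis = CubicSpline(ages, np.eye(len(ages)), bc_type="natural")
    return np.asarray(basis.integrate(lo, hi), float)


def spline_area_between(
    upper: AgeCurve, lower: AgeCurve, age_lo: float, age_hi: float
) -> float:
    """Signed area between two curves' natural-spline interpolants."""
    for c in (upper, lower):
        if not c.covers(age_lo, age_hi):
            raise ValueError(f"curve {c.label!r} does not cover [{age_lo}, {age_hi}]")
    if not np.array_equal(upper.ages, lower.ages):
        w_u = integration_weights(upper.ages, age_lo, age_hi)
        w_l = integration_weights(lower.ages, age_lo, age_hi)
        return float(w_u @ upper.mean - w_l @ lower.mean)
    w = integration_weights(upper.ages, age_lo, age_hi)
    return float(w @ (upper.mean - lower.mean))


def contribution_point(
    curve_1991: AgeCurve,
    curve_2011: AgeCurve,
    curve_no_statins: AgeCurve,
    age_lo: float,
    age_hi: float,
) -> tuple[float, float, float]:
    """Areas A and B and the deterministic fraction B / A."""
    area_a = spline_area_between(curve_1991, curve_2011, age_lo, age_hi)
    area_b = spline_area_between(curve_no_statins, curve_2011, age_lo, age_hi)
    if area_a == 0:
        raise ValueError("area A is zero; the contribution fraction is undefined")
    return area_a, area_b, area_b / area_a


def contribution_ui(
    curve_1991: AgeCurve,
    curve_2011: AgeCurve,
    curve_no_statins: AgeCurve,
    age_lo: float,
    age_hi: float,
    *,
    n_draws: int = DEFAULT_UI_DRAWS,
    seed: int | None = None,
    gap_curve: AgeCurve | None = None,
    rho: np.ndarray | None = None,
) -> ContributionEstimate:
    """Monte Carlo uncertainty interval for the contribution of three curves.

    Without ``gap_curve`` the three curves are perturbed independently
    (conservative; can yield artefactual negative bounds). Supplying the
    statin-gap curve (no-statins minus recent, with its own design SE) and
    optionally its per-age correlation ``rho`` with the recent curve switches
    to the linked propagation; see :func:`estimate_contribution`.
    """
    if n_draws < 100:
        logger.warning("n_draws=%d < 100; UI percentiles will be unstable", n_draws)
    mode = "independent" if gap_curve is None else "linked"
    if gap_curve is None:
        gap_curve = AgeCurve(
            label="statin_gap",
            ages=curve_2011.ages,
            mean=curve_no_statins.mean - curve_2011.mean,
            se=np.zeros_like(curve_2011.se),
            n=curve_2011.n,
        )
    if rho is None:
        rho = np.zeros(len(curve_2011.ages))
    cs = _CurveSet(
        curve_1991, curve_2011, gap_curve, curve_no_statins, rho, age_lo, age_hi
    )
    area_a, area_b = cs.areas_point()
    if area_a == 0:
        raise ValueError("area A is zero; the contribution fraction is undefined")
    rng = np.random.default_rng(seed)
    a, b = cs.areas_draws(rng, n_draws, mode)
    frac = b / a
    lo_q, hi_q = np.percentile(frac, [2.5, 97.5])
    return ContributionEstimate(
        point=area_b / area_a,
        ui_low=float(lo_q),
        ui_high=float(hi_q),
        mc_mean=float(frac.mean()),
        area_a=float(area_a),
        area_b=float(area_b),
        n_draws=n_draws,
        seed=seed,
    )


class _CurveSet:
    """Per-sex bundle of curves with shared integration weights."""

    def __init__(self, c1991, c2011, c_gap, c_nostat, rho, lo, hi):
        self.c1991, self.c2011 = c1991, c2011
        self.c_gap, self.c_nostat = c_gap, c_nostat
        self.rho = rho  # per-age corr(recent, gap)
        self.w = integration_weights(c2011.ages, lo, hi)
        self.w91 = (
            self.w
            if np.array_equal(c1991.ages, c2011.ages)
            else integration_weights(c1991.ages, lo, hi)
        )

    def areas_point(self) -> tuple[float, float]:
        a = float(self.w91 @ self.c1991.mean - self.w @ self.c2011.mean)
        b = float(self.w @ self.c_gap.mean)
        return a, b

    def areas_draws(self, rng, n_draws, mode) -> tuple[np.ndarray, np.ndarray]:
        def perturb(curve, w):
            noise = rng.standard_normal((n_draws, len(curve.mean)))
            return (curve.mean + noise * curve.se) @ w

        i91 = perturb(self.c1991, self.w91)
        if mode == "linked":
            # joint (recent, gap) draws with the estimated per-age correlation
            xi1 = rng.standard_normal((n_draws, len(self.c2011.mean)))
            xi2 = rng.standard_normal((n_draws, len(self.c2011.mean)))
            i11 = (self.c2011.mean + xi1 * self.c2011.se) @ self.w
            mix = self.rho * xi1 + np.sqrt(1.0 - self.rho**2) * xi2
            b = (self.c_gap.mean + mix * self.c_gap.se) @ self.w
        elif mode == "independent":
            i11 = perturb(self.c2011, self.w)
            ins = perturb(self.c_nostat, self.w)
            b = ins - i11
        else:
            raise ValueError("mode must be 'linked' or 'independent'")
        a = i91 - i11
        return a, b


def _curve_sets(
    participants: pd.DataFrame,
    *,
    sexes,
    qimd,
    age_range,
    min_n,
    single_psu,
) -> list[_CurveSet]:
    if "tc_scenario" not in participants.columns:
        raise ValueError(
            "participants lack a tc_scenario column; apply the no-statins "
            "scenario first"
        )
    lo, hi = age_range
    df = participants
    d91 = df[df["period"] == PERIOD_1991]
    d11 = df[df["period"] == PERIOD_2011]
    if qimd is not None:
        d11 = d11[d11["qimd"] == qimd]
    d11 = d11.copy()
    d11["tc_gap"] = d11["tc_scenario"] - d11["tc_mmol"]
    sets = []
    for sex in sexes:
        kw = dict(sex=sex, age_range=age_range, min_n=min_n, single_psu=single_psu)
        c91 = build_age_curve(d91, "tc_mmol", label="observed_1991", **kw)
        c11, cgap, rho = build_age_curve_pair(
            d11, "tc_mmol", "tc_gap",
            labels=("observed_2011", "statin_gap_2011"), **kw,
        )
        cns = build_age_curve(d11, "tc_scenario", label="no_statins_2011", **kw)
        sets.append(_CurveSet(c91, c11, cgap, cns, rho, lo, hi))
    return sets


def estimate_contribution(
    participants: pd.DataFrame,
    *,
    sexes=("male", "female"),
    qimd: int | None = None,
    age_range: tuple[int, int] = DEFAULT_AGE_RANGE,
    n_draws: int = DEFAULT_UI_DRAWS,
    seed: int | None = None,
    mode: str = "linked",
    min_n: int = 2,
    single_psu: str = "center",
) -> ContributionEstimate:
    """Statin contribution to the cholesterol decline, with a 95% UI.

    Requires the ``tc_scenario`` column (see
    :func:`statincf.counterfactual.apply_no_statins_scenario`). Curves are
    built per sex (the baseline 1991-92 curve always from the full baseline
    sample, the recent curves restricted to ``qimd`` when given) and the areas
    are summed over the requested sexes before taking the ratio.
    """
    if n_draws < 100:
        logger.warning("n_draws=%d < 100; UI percentiles will be unstable", n_draws)
    sets = _curve_sets(
        participants,
        sexes=sexes,
        qimd=qimd,
        age_range=age_range,
        min_n=min_n,
        single_psu=single_psu,
    )
    area_a = sum(s.areas_point()[0] for s in sets)
    area_b = sum(s.areas_point()[1] for s in sets)
    if area_a == 0:
        raise ValueError("area A is zero; the contribution fraction is undefined")
    point = area_b / area_a
    rng = np.random.default_rng(seed)
    a_draws = np.zeros(n_draws)
    b_draws = np.zeros(n_draws)
    for s in sets:
        a, b = s.areas_draws(rng, n_draws, mode)
        a_draws += a
        b_draws += b
    frac = b_draws / a_draws
    lo_q, hi_q = np.percentile(frac, [2.5, 97.5])
    return ContributionEstimate(
        point=point,
        ui_low=float(lo_q),
        ui_high=float(hi_q),
        mc_mean=float(frac.mean()),
        area_a=float(area_a),
        area_b=float(area_b),
        n_draws=n_draws,
        seed=seed,
    )


def stratified_contribution(
    participants: pd.DataFrame,
    *,
    sexes=("male", "female"),
    age_range: tuple[int, int] = STRATIFIED_AGE_RANGE,
    n_draws: int = DEFAULT_UI_DRAWS,
    seed: int | None = None,
    mode: str = "linked",
    **kwargs,
) -> tuple[pd.DataFrame, float, float]:
    """Contribution per QIMD quintile plus a Cochran-Armitage trend test.

    Each quintile uses its own recent and no-statins curves but shares the
    overall baseline curve (the baseline sample carries no QIMD and is assumed
    to have no socioeconomic cholesterol gradient). The analysis is restricted
    to ages 18-75 by default. The trend test is applied to the per-quintile
    statin user / non-user counts underlying the estimates; empty or
    uncoverable quintiles are skipped with a warning.
    """
    ss = np.random.SeedSequence(seed)
    level_seeds = ss.spawn(5)
    rows = []
    for q, sub_ss in zip(range(1, 6), level_seeds):
        try:
            est = estimate_contribution(
                participants,
                sexes=sexes,
                qimd=q,
                age_range=age_range,
                n_draws=n_draws,
                seed=int(sub_ss.generate_state(1)[0] % (2**31)),
                mode=mode,
                **kwargs,
            )
        except ValueError as exc:
            logger.warning("QIMD %d skipped: %s", q, exc)
            continue
        rows.append(
            {
                "qimd": q,
                "point": est.point,
                "ui_low": est.ui_low,
                "ui_high": est.ui_high,
                "area_a": est.area_a,
                "area_b": est.area_b,
            }
        )
    table = pd.DataFrame(rows)
    lo, hi = age_range
    d11 = participants[
        (participants["period"] == PERIOD_2011)
        & (participants["age"] >= lo)
        & (participants["age"] <= hi)
        & participants["sex"].isin(sexes)
        & participants["qimd"].notna()
    ]
    counts = np.zeros((2, 5))
    for q in range(1, 6):
        sub = d11[d11["qimd"] == q]
        users = int(sub["statin_user"].sum())
        counts[0, q - 1] = users
        counts[1, q - 1] = len(sub) - users
    z, p = cochran_armitage(counts)
    return table, float(z), float(p)


def sensitivity_inflate(pooled: PooledEffect, factor: float = 10.0) -> PooledEffect:
    """The pooled effect with its standard error inflated by ``factor``."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    return PooledEffect(e_w=pooled.e_w, se=pooled.se * factor)
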