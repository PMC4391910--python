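"""Design-aware survey estimation.

Point estimates are Hajek-type weighted means; variances use first-order Taylor
linearisation with stratified between-PSU sums of squares, the standard
complex-survey estimator (and what the R ``survey`` package computes by
default). Proportion CIs use the incomplete-beta (Clopper-Pearson at effective
sample size) method. Socioeconomic gradients are tested with survey-weighted
GLM slopes (Gaussian or binomial) using linearised sandwich SEs, and with the
two-tailed Cochran-Armitage trend test for binary outcomes across ordered
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

_Z95 = float(stats.norm.ppf(0.975))

#: numeric coding of the 1991-92 occupational social classes, "Other" last
SOCIAL_CLASS_RANK = {"I": 1, "II": 2, "IIIN": 3, "IIIM": 4, "IV": 5, "V": 6, "Other": 7}
#: robustness variant with "Other" placed before all other groups
SOCIAL_CLASS_RANK_OTHER_FIRST = {
    "Other": 1, "I": 2, "II": 3, "IIIN": 4, "IIIM": 5, "IV": 6, "V": 7
}


@dataclass(frozen=True)
class MeanEstimate:
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ProportionEstimate:
    p: float
    ci_low: float
    ci_high: float
    n_effective: float


@dataclass(frozen=True)
class SlopeEstimate:
    beta: float
    se: float
    p_value: float
    family: str


def _linearised_cov(
    Z: np.ndarray,
    psu: np.ndarray,
    stratum: np.ndarray,
    single_psu: str = "center",
) -> np.ndarray:
    """Stratified between-PSU covariance of totals of linearised scores.

    ``Z`` is (n, k); the result is the k x k design-based covariance of the k
    score totals. ``single_psu`` controls strata containing one PSU: "center"
    measures their deviation from the grand mean of PSU totals (logged),
    "certainty" makes them contribute zero.
    """
    if single_psu not in ("center", "certainty"):
        raise ValueError(f"unknown single-PSU policy {single_psu!r}")
    Z = np.asarray(Z, float)
    if Z.ndim != 2:
        raise ValueError("Z must be (n, k)")
    k = Z.shape[1]
    s_idx = pd.factorize(stratum)[0].astype(np.int64)
    p_idx = pd.factorize(psu)[0].astype(np.int64)
    pair = s_idx * (p_idx.max() + 1) + p_idx
    pair_u, pair_inv = np.unique(pair, return_inverse=True)
    totals = np.column_stack(
        [np.bincount(pair_inv, weights=Z[:, j]) for j in range(k)]
    )
    pair_strat = pair_u // (p_idx.max() + 1)
    n_h = np.bincount(pair_strat)
    mean_h = np.zeros((len(n_h), k))
    for j in range(k):
        with np.errstate(invalid="ignore"):
            mean_h[:, j] = np.bincount(pair_strat, weights=totals[:, j]) / np.maximum(
                n_h, 1
            )
    dev = totals - mean_h[pair_strat]
    cov = np.zeros((k, k))
    factor = np.where(n_h >= 2, n_h / np.maximum(n_h - 1.0, 1.0), 0.0)
    fp = factor[pair_strat]
    cov += (dev * fp[:, None]).T @ dev
    single = n_h == 1
    n_single = int(single.sum())
    if n_single and single_psu == "center":
        grand_mean = totals.mean(axis=0)
        lone = np.isin(pair_strat, np.flatnonzero(single))
        d = totals[lone] - grand_mean
        cov += d.T @ d
    if n_single:
        logger.info(
            "%d single-PSU stratum(s); handled with policy %r", n_single, single_psu
        )
    return cov


def _linearised_variance(z, psu, stratum, single_psu: str = "center") -> float:
    return float(_linearised_cov(np.asarray(z, float)[:, None], psu, stratum,
                                 single_psu)[0, 0])


def weighted_mean(
    values,
    weights=None,
    psu=None,
    stratum=None,
    *,
    single_psu: str = "center",
    level: float = 0.95,
) -> MeanEstimate:
    """Survey-weighted mean with a design-based (Taylor-linearised) SE.

    With unit weights, one stratum and each observation its own PSU this
    reduces to the textbook mean with SE ``s / sqrt(n)`` (``s`` the sample SD
    with the ``n - 1`` denominator).
    """
    y = np.asarray(values, float)
    n = len(y)
    if n == 0:
        raise ValueError("no observations")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if len(w) != n or (w < 0).any():
        raise ValueError("weights must be non-negative and match values")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("sum of weights must be positive")
    psu = np.arange(n) if psu is None else np.asarray(psu)
    stratum = np.zeros(n, dtype=int) if stratum is None else np.asarray(stratum)
    mean = float((w * y).sum() / wsum)
    if n == 1:
        se = 0.0
    else:
        z = w * (y - mean) / wsum
        se = float(np.sqrt(_linearised_variance(z, psu, stratum, single_psu)))
    zq = float(stats.norm.ppf(0.5 + level / 2))
    return MeanEstimate(mean, se, mean - zq * se, mean + zq * se, n)


def weighted_mean_pair(
    values_1,
    values_2,
    weights=None,
    psu=None,
    stratum=None,
    *,
    single_psu: str = "center",
    level: float = 0.95,
) -> tuple[MeanEstimate, MeanEstimate, float]:
    """Two survey-weighted means from the same sample, with their design-based
    sampling covariance (Taylor linearisation, shared PSU/stratum structure).

    Returns ``(estimate_1, estimate_2, cov)``.
    """
    y1 = np.asarray(values_1, float)
    y2 = np.asarray(values_2, float)
    n = len(y1)
    if len(y2) != n or n == 0:
        raise ValueError("values must be equal-length and non-empty")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("sum of weights must be positive")
    psu = np.arange(n) if psu is None else np.asarray(psu)
    stratum = np.zeros(n, dtype=int) if stratum is None else np.asarray(stratum)
    m1 = float((w * y1).sum() / wsum)
    m2 = float((w * y2).sum() / wsum)
    if n == 1:
        cov = np.zeros((2, 2))
    else:
        Z = np.column_stack([w * (y1 - m1) / wsum, w * (y2 - m2) / wsum])
        cov = _linearised_cov(Z, psu, stratum, single_psu)
    se1, se2 = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    zq = float(stats.norm.ppf(0.5 + level / 2))
    est1 = MeanEstimate(m1, se1, m1 - zq * se1, m1 + zq * se1, n)
    est2 = MeanEstimate(m2, se2, m2 - zq * se2, m2 + zq * se2, n)
    return est1, est2, float(cov[0, 1])


def weighted_proportion(
    flags, weights=None, psu=None, stratum=None, **kwargs
) -> MeanEstimate:
    """Design-based estimate of a proportion (weighted mean of a 0/1 flag)."""
    return weighted_mean(np.asarray(flags, float), weights, psu, stratum, **kwargs)


def proportion_ci(
    p: float, variance: float, n: int, level: float = 0.95
) -> ProportionEstimate:
    """Incomplete-beta CI for a survey proportion at effective sample size.

    ``n_eff = p(1-p)/var(p)`` (capped at the actual ``n``); the interval
    endpoints are the Clopper-Pearson beta quantiles evaluated at ``n_eff``
    and ``x_eff = p * n_eff``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    alpha = 1.0 - level
    if p in (0.0, 1.0):
        n_eff = float(n)
    else:
        if variance <= 0:
            raise ValueError("variance must be positive for 0 < p < 1")
        n_eff = min(p * (1 - p) / variance, float(n))
    x = p * n_eff
    low = 0.0 if x <= 0 else float(stats.beta.ppf(alpha / 2, x, n_eff - x + 1))
    high = 1.0 if x >= n_eff else float(stats.beta.ppf(1 - alpha / 2, x + 1, n_eff - x))
    return ProportionEstimate(p=p, ci_low=low, ci_high=high, n_effective=n_eff)


def design_proportion_ci(
    flags, weights=None, psu=None, stratum=None, level: float = 0.95, **kwargs
) -> ProportionEstimate:
    """Proportion CI straight from microdata with the design variance."""
    est = weighted_proportion(flags, weights, psu, stratum, **kwargs)
    return proportion_ci(est.mean, est.se**2, est.n, level)


def _sandwich_glm(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    family: str,
    psu: np.ndarray,
    stratum: np.ndarray,
    single_psu: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Survey-weighted GLM point fit plus linearised (sandwich) covariance."""
    fam = {"gaussian": sm.families.Gaussian(), "binomial": sm.families.Binomial()}[
        family
    ]
    fit = sm.GLM(y, X, family=fam, var_weights=w).fit()
    beta = np.asarray(fit.params)
    mu = np.asarray(fit.mu)
    # canonical links: score_i = w_i (y_i - mu_i) x_i ; info A = X' diag(w v) X
    v = np.ones_like(mu) if family == "gaussian" else mu * (1 - mu)
    A = X.T @ (X * (w * v)[:, None])
    scores = X * (w * (y - mu))[:, None]
    k = X.shape[1]
    sdf = pd.DataFrame({"stratum": stratum, "psu": psu})
    G = np.zeros((k, k))
    totals = (
        pd.concat([sdf, pd.DataFrame(scores)], axis=1)
        .groupby(["stratum", "psu"], sort=False)
        .sum()
    )
    grand_mean = totals.mean(axis=0).to_numpy()
    for _, t in totals.groupby(level="stratum", sort=False):
        th = t.to_numpy()
        n_h = th.shape[0]
        if n_h >= 2:
            d = th - th.mean(axis=0)
            G += n_h / (n_h - 1.0) * d.T @ d
        elif single_psu == "center":
            d = th - grand_mean
            G += d.T @ d
    Ainv = np.linalg.pinv(A)
    cov = Ainv @ G @ Ainv
    return beta, cov


def fit_gradient_slope(
    participants: pd.DataFrame,
    outcome: str,
    ses: str = "auto",
    family: str = "gaussian",
    adjust: tuple[str, ...] = (),
    *,
    other_first: bool = False,
    single_psu: str = "center",
) -> SlopeEstimate:
    """Socioeconomic-gradient slope from a survey-weighted GLM.

    The SES indicator (QIMD 1..5 or social class I..V/'Other' coded 1..7) enters
    as a numeric covariate; its slope, linearised SE and two-sided normal-based
    p-value measure the gradient. ``adjust`` may add "age" and/or "sex".
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    df = participants
    if ses == "auto":
        ses = "qimd" if df["qimd"].notna().any() else "social_class"
    if ses == "qimd":
        rank = df["qimd"].astype(float)
    elif ses == "social_class":
        table = SOCIAL_CLASS_RANK_OTHER_FIRST if other_first else SOCIAL_CLASS_RANK
        rank = df["social_class"].map(table).astype(float)
    else:
        raise ValueError("ses must be 'qimd', 'social_class' or 'auto'")
    y = df[outcome].astype(float).to_numpy()
    keep = np.isfinite(y) & np.isfinite(rank.to_numpy())
    df, y, rank = df.loc[keep], y[keep], rank.to_numpy()[keep]
    if len(df) == 0:
        raise ValueError("no complete cases for the gradient model")
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    if family == "binomial" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("binomial family requires a 0/1 outcome")
    cols = [np.ones(len(df)), rank]
    for cov in adjust:
        if cov == "age":
            cols.append(df["age"].astype(float).to_numpy())
        elif cov == "sex":
            cols.append((df["sex"] == "male").astype(float).to_numpy())
        else:
            raise ValueError(f"unknown adjustment covariate {cov!r}")
    X = np.column_stack(cols)
    w = df["weight"].astype(float).to_numpy()
    beta, cov = _sandwich_glm(
        y, X, w, family, df["psu"].to_numpy(), df["stratum"].to_numpy(), single_psu
    )
    b = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    p = 1.0 if se == 0 and b == 0 else 2 * float(stats.norm.sf(abs(b) / se)) if se > 0 else 0.0
    return SlopeEstimate(beta=b, se=se, p_value=p, family=family)


def cochran_armitage(
    counts,
    scores=None,
    *,
    method: str = "asymptotic",
    n_perm: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-tailed Cochran-Armitage trend test on a 2 x k table.

    ``counts`` has successes in row 0 and failures in row 1, columns ordered by
    SES rank. Returns the signed trend statistic Z and its two-sided p-value
    (normal reference, or a Monte Carlo permutation p conditioning on the
    margins with ``method="permutation"``).
    """
    tab = np.asarray(counts, float)
    if tab.ndim != 2 or tab.shape[0] != 2 or tab.shape[1] < 2:
        raise ValueError("counts must be a 2 x k table with k >= 2")
    if (tab < 0).any() or not np.allclose(tab, np.round(tab)):
        raise ValueError("counts must be non-negative integers")
    k = tab.shape[1]
    n_col = tab.sum(axis=0)
    if (n_col == 0).any():
        raise ValueError("zero column total")
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    r = tab[0]
    N = tab.sum()
    R = r.sum()
    pbar = R / N

    def _stat(successes: np.ndarray) -> np.ndarray:
        num = (s * (successes - pbar * n_col)).sum(axis=-1)
        den = pbar * (1 - pbar) * ((s**2 * n_col).sum() - (s * n_col).sum() ** 2 / N)
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / np.sqrt(den)

    z = float(_stat(r))
    if method == "asymptotic":
        p = 2 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(
            n_col.astype(int), int(R), size=n_perm
        ).astype(float)
        zs = _stat(draws)
        p = float((np.abs(zs) >= abs(z) - 1e-12).mean())
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    if not np.isfinite(z):
        z, p = 0.0, 1.0
    return z, min(p, 1.0)
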