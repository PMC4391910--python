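# Methods

This note documents the model implemented by `statincf`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Setting and estimand

Two cross-sectional health-examination surveys of the adult (18+) English
population are compared: an unweighted early-1990s baseline and a weighted
2011-12-like sample with a stratified, clustered design (strata and primary
sampling units, PSUs). The quantity of interest is the share of the observed
decline in population mean serum total cholesterol (TC, mmol/L) that is
attributable to statin use, overall, by sex, and by deprivation quintile
(QIMD, 1 = most affluent). The counterfactual is a "no statins" population in
which every user's TC is restored to its untreated value and everything else
is unchanged.

## Pooled statin effect E_w

Surveys record statin use (any statin taken in the 7 days before interview,
prescribed or over the counter) but not the product or dose. The
population-average proportional TC reduction among users is therefore the
dispensing-weighted mean over product x strength cells,
`E_w = Σ M_ij E_ij / Σ M_ij`, with units `M_ij` from national dispensing
statistics (one tablet or 5 ml of liquid = one unit).

* **Inputs.** Per-statin proportional LDL reductions with 95% CIs are taken
  from the Law, Wald & Rudnicka (2003) meta-analysis, which standardises
  absolute reductions to a pre-treatment LDL of 4.8 mmol/L; SEs are recovered
  from the CIs assuming normality. The bundled dispensing file is an
  approximate reconstruction of the England 2011+2012 Prescription Cost
  Analysis volumes, scaled to the published total of ~4.07 billion units, and
  is labelled synthetic accordingly; users with access to the source data
  can supply their own CSVs.
* **LDL to TC conversion.** Statins act almost entirely on LDL, so the
  absolute TC fall equals the absolute LDL fall and the proportional
  conversion factor is the LDL share of TC at the trial baseline:
  4.8 / (4.8 + HDL ~1.3 + TG/2.2 ~0.8) ≈ 0.70. The factor is a single
  configurable scalar; no per-statin variation is modelled.
* **Untrialled strengths** (e.g. atorvastatin 30 mg) are predicted from a
  per-statin weighted least-squares fit of the TC reduction on ln(strength)
  with inverse-variance weights; the prediction-mean SE uses the coefficient
  covariance with the usual residual-scale estimate (zero for a saturated
  two-point fit). Measured strengths are never overwritten. Fitting is per
  statin, not pooled across statins, since potency differs by an order of
  magnitude between products.
* **Form rules.** Solid and liquid forms are treated as equally effective;
  simvastatin-ezetimibe combinations are re-labelled as plain simvastatin of
  the same strength before pooling, conserving units.
* **se(E_w)** uses Cochran's frequency-weighted-mean formula in the Gatz &
  Smith (1995) formulation, computed over product x strength cells (not
  individual prescription items). The three-term textbook expression
  collapses algebraically to `sqrt(n/(n-1)) * sqrt(Σ w²(x - x̄_w)²) / Σw`,
  which is what the code evaluates; the tests keep the three-term form as an
  independent oracle. With the bundled tables this gives
  E_w = 0.254, se = 0.011.

## The counterfactual scenario

Each user's predicted untreated cholesterol is `TC_obs / (1 - E_w)`.
Uncertainty in E_w is propagated per user by averaging `TC_obs / (1 - e_k)`
over `n_draws = 1000` normal draws `e_k ~ N(E_w, se)`; draws at or above 1,
or at or below a configurable floor (default -1), are rejected and redrawn
with the count logged. Because `1/(1-e)` is convex the Monte Carlo mean
exceeds the plug-in value by a relative `~se²/(1-E_w)²` (Jensen), which is
negligible (~2x10⁻⁴) at the estimated se but grows quadratically when the se
is inflated — see the sensitivity section. Non-users and users without a
cholesterol measurement are untouched. One global E_w is applied to every
user regardless of product; this is the model's central approximation, forced
by the absence of per-respondent product information.

With `se = 0` the scenario is applied in closed form, making the
reduction-then-removal round trip exact to machine precision.

## Survey estimation

* **Means.** Hajek-type weighted means; variances by first-order Taylor
  linearisation with stratified between-PSU sums of squares (the standard
  complex-survey estimator and the default of the R `survey` package).
  Strata represented by a single PSU are centred at the grand mean of PSU
  totals by default ("certainty" is available); occurrences are logged.
  With unit weights and independent PSUs the estimator reduces to the
  textbook `s/sqrt(n)`.
* **Proportions.** CIs use the incomplete-beta method at effective sample
  size `n_eff = p(1-p)/var(p̂)` (capped at n), i.e. Clopper-Pearson beta
  quantiles evaluated at `n_eff` and `x_eff = p n_eff`; the strict analogue
  (no midpoint correction) is used. Under simple random sampling this is
  exactly Clopper-Pearson.
* **Socioeconomic gradients.** Survey-weighted Gaussian (cholesterol) or
  binomial (statin use) GLMs with the SES indicator as a numeric covariate
  (QIMD 1-5; social classes I, II, IIIN, IIIM, IV, V, Other coded 1-7, with
  a flag to move Other first as a robustness check), optionally adjusted
  additively for age and sex. Coefficient SEs are linearised sandwich
  estimates clustered by PSU within strata; p-values use the normal
  reference.
* **Trend across quintiles.** The two-tailed Cochran-Armitage test with
  equally spaced scores, applied to the user/non-user counts underlying each
  quintile; a Monte Carlo permutation p (conditioning on the margins via
  multivariate hypergeometric draws) is available for small tables. The test
  addresses the statin-use trend that drives the contribution gradient; the
  contribution fractions themselves are continuous and carry no exact trend
  test.

## Age curves and the area statistic

Design-based mean TC is computed per single year of age from 18 to 89, with
everyone aged 89+ pooled into the top bin (very few respondents are older).
Ages with fewer than two respondents keep their point estimate but borrow the
SE (and correlation) of the nearest adequately sized age. Natural cubic
splines are fitted through each curve's per-age means and integrated in
closed form; because spline fitting and integration are linear in the means,
each curve's integral is a fixed weight vector dotted with its means, which
the Monte Carlo exploits. Areas are signed: ranges where the baseline dips
below the recent curve subtract, keeping area A interpretable as the net
decline. Areas are computed per sex and summed over sexes before the ratio.

The equipment change of April 2010 raised measured TC by 0.1 mmol/L;
flagged measurements are corrected once (an idempotence guard refuses double
application) before any estimation.

### Uncertainty intervals

For each of 10,000 draws, every age's mean is perturbed by its design-based
SE, splines are refitted (implicitly, via the weight vectors), and the
fraction recomputed; the 2.5/97.5 percentiles form the 95% UI. The headline
point estimate is the deterministic spline fraction; the Monte Carlo mean is
reported alongside (the two agree to ~0.01% in practice).

The default propagation, `mode="linked"`, recognises that the recent and
no-statins curves come from the same respondents: it perturbs the baseline
curve independently and the (recent, statin-gap) pair jointly, using the
per-age linearised covariance between the observed mean and the mean
scenario-minus-observed gap, then reconstructs the no-statins curve as
recent + gap. The gap is *negatively* correlated with the recent curve (a
chance excess of users lowers the observed mean and raises the gap at once),
and ignoring the linkage roughly doubles the implied variance of area B. In
recovery experiments the linked UI is well calibrated (UI-implied SD 0.0081
vs empirical replicate SD 0.0079 at the default configuration).
`mode="independent"` perturbs all three curves independently; it is markedly
conservative and can produce artefactual negative lower bounds when curve
CIs overlap, but is retained for comparability with analyses that treated
the curves as independent.

### QIMD stratification

Per quintile, the recent and no-statins curves are quintile-specific while
the baseline curve is the overall (sex-specific) baseline curve, under the
assumption — supported by the gradient test on the baseline sample — that
cholesterol had no socioeconomic gradient at baseline, whose survey lacks
QIMD entirely. The stratified analysis is restricted to ages 18-75 because
older quintile cells are sparse; quintiles with empty cells are skipped with
a warning rather than failing the run.

## Sensitivity analysis

The pipeline is re-run with se(E_w) multiplied by 10 (point estimate
unchanged). Through the Jensen term above, a tenfold se multiplies the
per-user mean rescale factor's excess by ~1 + 99·se²/(1-E_w)², inflating
area B by roughly 8-10% at the bundled-table uncertainty and shifting the
contribution point estimate by about +2.7 percentage points in the default
synthetic configuration (31.4% -> 34.1%). This shift is a mathematical
consequence of averaging a convex function over wider draws, not a numerical
artefact: no rejection/truncation policy removes it, and any
mean-over-normal-draws implementation of the scenario must reproduce it. The
UI width is essentially unchanged, since the interval is driven by the
age-curve SEs rather than by se(E_w).

## Synthetic data: what it emulates and what it does not

The generator draws, per period: age (group probabilities with a linearly
thinning 55+ tail), sex, QIMD or social class, a stratified PSU assignment
with a small PSU-level cholesterol intercept (SD 0.06 mmol/L, inducing a
mild design effect), counterfactual TC ~ Normal(m(age, sex) + trend + QIMD
shift, 1.05), statin use from a logistic model in age group, sex and QIMD,
users' observed TC = counterfactual x (1 - true_effect), lognormal survey
weights (mean 1; unit weights at baseline), the +0.1 mmol/L analyser offset
on recorded recent-period values, and 29% missing cholesterol at random.
Default parameters are calibrated to published HSE 1991-2012 summary tables:
anchor means (e.g. men 5.20/5.97/6.10 at ages 26/45/67 at baseline), secular
trends chosen so observed recent-period group means land near their
published values given the prevalence model, prevalence ~13.3% overall with
a log-odds QIMD slope of 0.12, and true_effect = 0.257. The generative
contribution of statins to the decline is ~31.9% at the defaults, computed
analytically by applying the same spline-area statistic to the exact
expected curves.

Deliberately not emulated: the real sampling frame and geography,
non-response mechanisms (weights are noise, not calibration), within-period
time trends, per-product statin assignment, adherence, and confounding by
indication (a logit-per-mmol/L knob exists, default off, to let experiments
quantify the bias the method cannot remove; the analytic ground truth is
valid only with the knob off). Passing recovery tests therefore show that
the curve/area/Monte-Carlo machinery is unbiased and calibrated under the
model's own assumptions — not that those assumptions hold in real survey
data, where confounding by indication biases the no-statins curve upward for
sicker users.

## Numerical choices and degenerate inputs

* Single master seed -> named per-stage sub-streams (SHA-256 of
  "seed:stage"), so the stratified run never perturbs the overall run's
  draws and every stage replays independently; per-quintile seeds spawn from
  the stratified stream.
* Spline integration is exact piecewise-polynomial quadrature of the natural
  cubic interpolant (no sampling); area additivity over sub-ranges holds to
  1e-9 relative.
* Rejection sampling for effect draws caps at 100 rounds (unreachable for
  any sane (E_w, se)); a >1% rejection rate logs a mis-specification
  warning.
* Zero-unit dispensing cells are ignored; duplicate cells are merged by
  summing units (invariant by construction); an all-zero table is an error.
* Empty single-year age cells are an error for the overall analysis and a
  logged skip for quintile strata; at the default n = 20,000 per period all
  cells are occupied.
* Proportion CIs at p̂ ∈ {0, 1} pin the corresponding bound to the boundary.
* Percentages are reported to 1-2 decimals and cholesterol to 2-3, matching
  the precision conventions of the survey literature.

## Problem sizes

Default experiment sizes were chosen so the whole suite runs comfortably on
a laptop-class single core: 20,000 participants per period, 1,000 per-user
draws, 10,000 per-age UI draws for one-off analyses, 1,000 UI draws inside
the 200-replicate recovery study, and 100,000 permutations for the
trend-test oracle.
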