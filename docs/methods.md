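# Methods

`bathrisk` implements a two-stage analysis of the nonlinear association
between daily mean outdoor temperature and daily counts of bath-related
drowning deaths across administrative units (prefectures), together with a
synthetic cohort generator that stands in for the restricted
death-certificate data.

## Stage 1: penalized-spline quasi-Poisson GAM / GAMM

For unit *i* on day *d* with death count *y_id*, annual population *N_iy* and
daily mean temperature *T_id*, the model is

    log E[y_id] = alpha + f(T_id) + b_i + log N_iy,
    Var[y_id]   = phi * E[y_id],

where *f* is a penalized smooth, *b_i ~ N(0, sigma_u^2)* are unit random
intercepts (omitted in per-unit GAM fits), the log population is an offset so
coefficients act on per-person rates, and *phi* is a quasi-Poisson dispersion.
The population is treated as constant within a calendar year, matching how
annual census denominators are used in this literature.

**Basis and penalty.** *f* is a cubic B-spline with `k = 10` basis functions.
Interior knots sit at quantiles of the distinct observed exposures; boundary
knots just outside the observed range. A sum-to-zero constraint (the smooth
averages to zero over the fitting sample) is absorbed into the basis, leaving
`k - 1` columns next to an explicit intercept. The second-order difference
penalty is built from **divided differences at the Greville abscissae**, with
rows weighted by site spacing so the quadratic form approximates the
integrated squared second derivative. With raw (unscaled) coefficient
differences the penalty null space is "linear in coefficient index", which
under quantile knots is *not* the linear functions: in our experiments a
log-linear truth then retained EDF near 5 under REML. The divided-difference
form makes the null space exactly the linear functions for any knot layout
(verified to machine precision in the tests).

**Fitting.** Coefficients maximise the penalized quasi-Poisson log-likelihood
by penalized IRLS (PIRLS) with step-halving; convergence is a relative change
in penalized deviance below 1e-8 (at most 200 iterations; non-convergence
raises an error carrying the iteration trace). Random intercepts are
ridge-penalized dummy coefficients with ridge weight `lambda_u`; the implied
variance component is `sigma_u^2 = phi / lambda_u`.

**Smoothing-parameter selection.** `lambda` (and jointly `lambda_u` for the
GAMM) minimise an extended-quasi-likelihood REML criterion evaluated at the
converged fit:

    D_p / phi0 + (n - m) log(2 pi phi0) + log|X'WX + P| - log|P|_+ ,

with *D_p* the penalized deviance, *m* the dimension of the total penalty
null space, and `|P|_+` the pseudo-determinant of the penalty. The scale
`phi0` is estimated **once, by Pearson, from a low-smoothing pilot fit** and
held fixed across the search. Two alternatives were evaluated and rejected
during development: profiling the scale from the deviance under-estimates it
at the low daily means typical of this outcome (deviance residuals shrink as
the mean goes to 0), which over-weights misfit and under-smooths —
flat-truth simulations retained spurious EDF > 2 in about 60% of replicates;
re-estimating the Pearson scale at every candidate rewards shrinkage (a
worse fit inflates the scale that divides it) and collapsed the
random-intercept variance in recovery simulations. With the pilot-scale
criterion, recovery simulations give sigma_u 0.51 against a sample truth of
0.55, EDF 1.03 for a log-linear truth, and EDF 6.0 / 7.6 for the design
curve at n of roughly 95k / 446k unit-days. The search is a log10 grid
(-2..8, 15 points) refined by bounded golden-section; the GAMM optimises
(log lambda, log lambda_u) by a coarse grid plus Nelder-Mead.

**Reported quantities.** Dispersion is the Pearson statistic over `n - EDF`.
EDF of the smooth is the trace of the corresponding block of
`(X'WX + P)^{-1} X'WX` (1 means shrunk to a straight line; at most `k - 1`).
The coefficient covariance is the dispersion-scaled Bayesian form
`phi (X'WX + P)^{-1}`. Marginal and conditional R² follow the
variance-decomposition approach for log-link count mixed models: fixed
variance is the variance of intercept-plus-smooth over the observations,
random variance is `sigma_u^2`, and the observation-level variance is the
trigamma `psi_1(lambda_bar / phi)` at the mean fitted count; the smooth-term
p-value is a Wald-type statistic on the penalized coefficients with rank set
by the rounded-up EDF. Both are documented approximations, not exact tests.

## Exposure-response summaries

The fitted smooth is evaluated on a 0.1 °C grid spanning the 1st–99th
percentiles of the fit's own exposure sample (linear-interpolation
quantiles). The **reference temperature** is the grid minimiser of fitted
log risk (ties broken to the warmest point); `RR(T) = exp(f(T) − f(ref))`,
so the grid minimum of RR is exactly 1. The **peak RR** is the grid maximum
(ties to the coldest point), matching the cold-peak phenomenology of this
outcome.

Pointwise CIs use the normal approximation for the contrast `f(T) − f(ref)`.
The **peak-RR interval** draws `n_sim = 1000` coefficient vectors from the
posterior, recomputes the max–min log-risk range per draw (re-locating both
extremes, so location uncertainty is propagated), and forms the **basic
(pivotal) interval** `[2m − q97.5, 2m − q2.5]` around the point estimate
*m*. The raw percentile interval of the range statistic is bounded below by
1 in every draw and therefore can never cover RR = 1 under a flat truth
(measured 0/30 null coverage); the basic interval corrects the selection
bias of the range and achieved 92–96% null coverage across independent seed
families at the pooled-panel sizes where the pipeline uses it.
`ci_method="percentile"` exposes the raw variant. `se_log_peak_rr` is the SD
of the log range across draws.

## Stage 2: within/between mixed-effects meta-regression

For unit *i* and period *j* (default periods 1995–2003, 2004–2012,
2013–2020):

    log(RR_ij) = beta0 + beta1 (x_ij − x̄_i) + beta2 x̄_i + u_i + eps_ij,

with unit random intercepts and iid residuals. `beta1` is the within-unit
association, `beta2` the between-unit one. Estimation is REML for this small
linear mixed model, implemented directly (per-unit compound-symmetry blocks
via the Woodbury identity; Nelder-Mead on log variances from three starts);
it matches statsmodels' `MixedLM` to ~1e-5 and a dense-matrix grid-search
oracle to 1e-4 in the tests. A weighted variant treats the stage-1 sampling
variances `v_ij` as known per-row variances and estimates residual
heterogeneity `tau^2` on top; the default is unweighted, implementing the
model equation literally. One covariate is analysed per model.

Effects are reported per SD of the covariate: `exp(beta2 * sd_between)`
across unit means and `exp(beta1 * sd_within)` across centered values, with
delta-method CIs; SDs are computed on the analysis sample after missingness
exclusions. Covariates observed in a subset of periods contribute between
information only for the covered rows (no imputation); with no within-unit
variation the model drops `beta1` (between-only); with one row per unit the
two variance components are not separable and only their sum is estimated.

## Synthetic cohort generator

The generator emulates the statistical structure of the national panel:

- **Temperatures**: per unit, a sinusoid (coldest in late January) around an
  annual mean drawn uniformly on 9–23 °C (the cool-north/warm-south
  gradient), amplitude ~N(9.5, 0.8²) °C, plus a stationary AR(1) anomaly
  (rho 0.6, marginal SD 1.5 °C). Daily max/min are the mean ± independent
  gamma half-ranges (mean 4.2 °C), so ordering always holds and the diurnal
  range averages ~8.4 °C. The pooled panel reaches ~30–31 °C at its 99th
  percentile, so the design reference of 30.3 °C is inside the restricted
  range.
- **True curve**: log RR declines from `log(peak_rr)` at `peak_temp`
  (default 1.8 °C, peak RR 9.7) to 0 at `ref_temp` (30.3 °C) via a blend of
  a cubic smoothstep (steepest at mid-range temperatures, weight 0.65) and a
  quadratic (weight 0.35, keeping the slope at the reference nonzero so the
  minimum is identifiable); below the peak a mild quadratic decline
  (0.004/°C²) keeps the maximum at the peak temperature rather than the cold
  boundary; above the reference a mild uptick (0.02/°C²) keeps the minimum
  at the reference. These curvatures are identifiability choices of the
  ground-truth family, fixed before any recovery experiment.
- **Counts**: mean = population × baseline rate (3.5e-8 per person-day at
  the reference, giving roughly 0.2–0.6 deaths per unit-day, the order seen
  nationally) × exp(log risk + unit intercept), with gamma-mixed Poisson
  (negative binomial) noise whose size parameter `m/(phi−1)` matches
  `Var = phi·m` exactly for every mean. Default dispersion 1.3 — the real
  overdispersion magnitude is not characterised publicly, so this is a
  deliberate, documented choice. Unit random intercepts are N(0, 0.3²);
  populations log-uniform on 0.5–9 million, constant within a year.
- **Modifiers and truth**: each covariate has a unit-level mean N(20, 5²)
  plus period drift N(0, 1.5²); unit-period true log peak RRs are the global
  mean plus per-SD effects on the standardised covariate plus a unit
  deviation N(0, 0.15²), and are emitted in a truth table for recovery
  scoring (the standardisation constants ride along in
  `covariates.attrs["standardization"]`).

What the generator does **not** emulate: spatial correlation between units,
long-term mortality trends and ageing, day-of-week or holiday bathing
patterns, lagged temperature effects, age/sex structure (stratum labels are
out of scope), or real station temperature records. Passing recovery tests
therefore show that the estimators invert the generator's mechanism at
realistic information levels — not that the real-data estimates are correct.

## Problem sizes and reproducibility

Recovery and calibration studies run at sizes chosen to probe the regimes
that matter while keeping each study to seconds–minutes: stage-1 national
recovery uses 10 units × 26 years (~95k unit-days, ~25k deaths); null
calibration of the peak interval uses 50 replicates of pooled 5-unit ×
8-year panels; the Wald-size study uses 200 stage-2 replicates and the
stage-2 recovery 50 replicates at the full 47 × 3 layout. All randomness
flows from a single integer seed through `numpy.random.SeedSequence`
spawning; regenerating a cohort or re-running the pipeline with the same
seed reproduces output files byte-for-byte.

## Known limitations

- The REML surrogate for quasi-likelihood is an approximation; smoothing
  parameter uncertainty is not propagated into the coefficient covariance,
  which is part of why the peak interval needs the pivotal correction.
- The smooth-term p-value and the R² decomposition are approximate by
  construction.
- The peak interval's null coverage is ~92–95% at pooled-panel information
  levels but degrades toward ~90% for single sparse units.
- Per-SD ratios assume the covariate acts log-linearly on the peak RR; no
  multivariable meta-regression is provided.
- Lagged exposure effects and within-year population change are out of
  scope by design.
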