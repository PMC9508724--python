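# Methods

`lgmsens` implements a three-step sensitivity workflow for two-arm randomised
trials with a continuous repeated outcome (an AUDIT-C-like 0–12 score) at five
waves (0, 3, 6, 12, 36 months) and missing follow-ups: (1) missing-data
diagnostics, (2) latent growth models estimated by full-information maximum
likelihood (FIML) under a missing-at-random (MAR) assumption, and (3) three
families of growth models that allow the missingness to be not at random
(MNAR). Comparing the arm contrasts across all models shows how sensitive a
trial's conclusion is to the assumed missing-data mechanism.

## The growth model

For participant *i* with regressors *x<sub>i</sub>* (trial arm, optionally
baseline covariates),

η*<sub>i</sub>* = α + B x*<sub>i</sub>* + ζ*<sub>i</sub>*, ζ*<sub>i</sub>* ~ N(0, Ψ),
y*<sub>i</sub>* = Λ η*<sub>i</sub>* + e*<sub>i</sub>*, e*<sub>i</sub>* ~ N(0, diag(ε)),

with fixed loadings: intercept column all ones, linear column
(0, 0.1, 0.2, 0.4, 1.2) — one loading unit = 30 months — and quadratic column
its square. Marginally y*<sub>i</sub>* ~ N(Λ(α + Bx*<sub>i</sub>*),
ΛΨΛ′ + diag(ε)). FIML sums each participant's observed-subvector normal
log-density; participants are grouped by missing pattern so each pattern's
sub-covariance is factorised once. Analytic per-case scores are available for
every model in the package, so gradients, sandwich ("robust", A⁻¹BA⁻¹) and
first-order (inverse outer-product-of-scores) standard errors are exact up to
one finite-difference Hessian.

Parameterisation: Ψ through its Cholesky factor (positive semi-definite by
construction), residual variances on the log scale with box bounds
log ε ∈ [−12, 12] — a zero-variance (Heywood) boundary is representable
without numerical underflow. Optimisation is L-BFGS-B on the mean
log-likelihood (so gradient-norm thresholds are sample-size free), optionally
followed by a damped-Newton polish; `fit_mar` declares convergence at
relative log-likelihood change below 1e−13 and mean-scale gradient norm below
1e−5. Starting values are moment-based: baseline mean/variance for the
intercept factor, per-person OLS slopes through observed waves for the linear
factor, residual variances at half the baseline variance.

Arm contrasts at waves t3/t4: `diff(t) = β_I + λ_S(t) β_S + λ_Q(t) β_Q`
(positive = higher outcome in the intervention arm) and
`change_diff(t) = −(λ_S(t) β_S + λ_Q(t) β_Q)` (positive = stronger decrease in
the intervention arm), with delta-method 95% CIs. These satisfy
`diff(t) + change_diff(t) = β_I` identically. Because it is not obvious
whether a "group difference at follow-up" should include the arm effect on the
intercept factor (randomisation argues β_I ≈ 0), both the inclusive contrast
(primary) and a `diff_excl_intercept` variant are reported.

Fit indices use the unscaled likelihood-ratio statistic T = 2(LL_sat −
LL_model) against a saturated model (unstructured mean/covariance fitted by an
EM algorithm for incomplete multivariate-normal data, monotone likelihood,
convergence at relative change < 1e−10) and an independence baseline
(per-wave means and variances; closed form because the likelihood factorises
across waves). BIC = −2LL + p·ln N; CFI and RMSEA from T and df, RMSEA with
denominator N. A robust (mean-scaled) correction of the fit statistic is not
applied; robustness is carried by the sandwich standard errors, not the fit
indices. With covariates, the saturated and baseline models condition on the
same regressors.

## Step 1 — diagnostics

Missing-pattern enumeration (at most 16 patterns since baseline is always
observed), per-pattern mean trajectories by arm, observed descriptives
(per-cell means/SDs, n−1 divisor), and logistic regressions of participation
(outcome observed) at t3 and t4 on baseline covariates, fitted with
statsmodels; Wald CIs on the log-odds scale, exponentiated to odds ratios.
Smoking enters as a smoker-vs-non-smoker contrast by default (occasional or
daily vs never/former), full dummy categories optionally. Rows with missing
covariates are dropped listwise and the retained n is reported.

## Step 3 — MNAR models

Two indicator codings of the wave-wise missingness (waves t1..t4): under
**survival coding**, 1 marks the permanent-dropout event at the first wave of
the terminal missing run, 0 marks any earlier at-risk wave (observed or
intermittently missing), and waves after dropout are "not at risk" (internal
sentinel −1, written "NA"); under **multinomial coding** the at-risk waves
distinguish intermittent missing (0), dropout (1) and observed (reference, 2).

**Diggle-Kenward selection model.** Wave-wise logistic (or baseline-category
multinomial) regressions of the indicator on the concurrent outcome y_t and
previous outcome y_{t−1}, with wave-specific intercepts and slopes shared
across waves; the joint likelihood multiplies the FIML Gaussian factor with
the selection probabilities at every at-risk wave. Selection terms involving
missing outcomes are integrated against their conditional normal law given the
observed outcomes by Gauss-Hermite quadrature centred at the conditional mean
and scaled by the conditional Cholesky factor (15 nodes per dimension by
default; the integration dimension never exceeds 3 with five waves). Missing
outcomes that enter no selection term are marginalised analytically by the
Gaussian factor. Identification rests entirely on the multivariate-normality
assumption of the outcome vector. Per-wave slopes are not offered; the
shared-slope form is the model whose single concurrent-outcome coefficient the
workflow reports.

**Wu-Carroll shared-parameter model.** The indicators are regressed on the
latent intercept and slope; the quadratic factor is excluded from the
regression (the convention that rescues convergence) but kept in the growth
model, where it is absorbed exactly by the Gaussian factor. Because
missingness depends on the factors only, the likelihood factorises as
p(y_obs) · E[(I,S)|y_obs][∏ P(m_t|I,S)], and since every selection term
depends on (I,S) only through the linear predictors u = Γ′(I,S), the
expectation is evaluated on the exact conditional law of u — one-dimensional
under survival coding, two-dimensional under multinomial coding. Node
placement then scales with the spread of the linear predictor itself, which
keeps the quadrature accurate for arbitrarily steep coefficients.

The shared-parameter marginal likelihood has a known degenerate ridge: as
|γ| → ∞ the model becomes a deterministic threshold rule mapping the latent
slope to the dropout time, and in roughly 10% of N = 1000 synthetic replicates
that ridge dominated the interior optimum (verified against node-refined
quadrature and Monte-Carlo integration — the boundary likelihood is real).
`fit_wc` therefore treats any factor coefficient with |γ| > 3 (odds ratio
above 20 per factor-unit, substantively absurd) as a degenerate fit, drops
that factor from the selection regression with a warning, and refits —
mirroring the established practice of omitting factors from the regression to
obtain credible convergence. Both sandwich and first-order ("MLF"-style)
standard errors are computed; a relative disagreement above 25% triggers a
warning recommending the first-order flavour.

**Pattern-mixture models.** The sample is split into three observed classes:
*no_followup* (t3 and t4 both missing), *complete* (t1 and t2 both observed,
some follow-up), *intermittent* (the rest). The growth model is fitted per
class; parameters a class cannot identify are fixed by an identifying
restriction — complete-case (borrow from the complete class),
neighbouring-case (nearest richer class in the order complete > intermittent >
no_followup where the parameter is estimable), or available-case
(proportion-weighted average over the already-fitted classes where estimable).
Overall estimates are Σ π_k θ̂_k with sample class proportions π treated as
known in the delta-method SEs (a parametric-bootstrap alternative over the
class estimate distributions is provided and agrees for these linear
averages).

Inestimable-parameter detection combines three deterministic rules:

1. residual variances of waves no class member reached;
2. an interpolation rule — a polynomial factor of order f needs at least
   f + 1 distinct observed waves;
3. a *saturated-mean* rule — when the surviving factors exactly saturate the
   class's observed waves, the highest-order factor (never the intercept) is
   flagged as well. A just-identified mean curve is technically invertible
   (for waves 0/3/6 months the mean map determinant is 0.002) but so
   ill-conditioned that leaving it free produced averaged t4 contrasts with
   SEs near 7 score points; borrowing it yields follow-up CIs on the scale the
   method produces in practice (t4 SE ≈ 0.36 on emulated data);
4. finally, a class-wise Fisher-information rank test at a
   positive-definite-ridged reference point (relative eigenvalue < 1e−8),
   which catches covariance-side under-identification — e.g. the quadratic
   rows of Ψ in a three-wave class (6 observed moments vs 9 covariance
   parameters); null directions are attributed to single parameters by a
   fixed priority (covariances involving the highest-order factor first, then
   residual variances, then means).

Psi restrictions are escalated to whole factor rows (the higher-order factor
of a flagged covariance entry), so the restricted Ψ stays interpretable; the
free block remains on the Cholesky scale.

## Synthetic trial generator

The generator draws covariates (sex, age, education, partner, health,
smoking), assigns arms by balanced randomisation, draws factors from
N(α + Bx, Ψ) and outcomes y = Λη + e, then imposes missingness. Defaults
emulate a general-population brief-alcohol-intervention trial: N = 1646, 1:1
allocation, baseline mean 3.5 and SD 1.78 (ψ_I = 2.17, ε = 1 per wave),
slowly declining means (α = (3.5, −1.0333, 0.5833), the quadratic/linear pair
interpolating a decline to 3.18 at 12 months and 3.10 at 36 months in the
control arm) and a small positive arm effect on the follow-up difference
(arm effects (0, 0.293, −0.1886), i.e. +0.087 at t3). Outcomes are generated
unbounded by default, matching the estimators' normality assumption;
clamping/rounding to 0–12 is available as a deliberate misspecification mode.
Covariate effects on the outcome are off by default so that the generating
parameters coincide with the fitted unadjusted model's parameters; the MAR
mechanism still depends on the covariates and the most recent observed
outcome, so it is genuinely MAR rather than MCAR.

Missingness mechanisms: MCAR (independent per-cell masking), MAR (wave-wise
dropout hazard on age, education, smoking, baseline risk and the last
observed outcome), MNAR_DK (hazard on the true previous and concurrent
outcomes, default slope 0.3 on the concurrent outcome) and MNAR_WC (hazard on
the true latent intercept/slope, default 0.12 on the intercept). Intermittent
misses are layered first with independent probability 0.03 per wave; dropout
dominates and masks all later waves. Hazard intercepts were calibrated once
by large-sample root-finding so each mechanism reproduces retention of
approximately 85/81/80/65% at t1..t4, and are frozen in the source. Random
draws are split into per-purpose substreams (covariates, factors, residuals,
missingness) so mechanisms can be swapped holding the complete outcomes
fixed.

What the generator does *not* emulate: bounded/discrete scores (unless the
misspecification mode is chosen), covariate-outcome confounding,
non-normal trajectory heterogeneity, and time-varying covariates. Passing
recovery tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to violations of them.

## Verification design and problem sizes

Every likelihood has an independent oracle test: FIML against per-case scipy
multivariate-normal densities (1e−10); Diggle-Kenward and Wu-Carroll per-case
contributions against 10⁶-draw Monte-Carlo integration (1e−3) on five
mixed-pattern fixtures each; quadrature stability under node doubling; exact
separability onto the MAR fit when selection coefficients are fixed at zero.
Parameter recovery runs the matched estimator on each mechanism:

- MAR: 300 replicates at N = 500; each growth-curve fixed effect's mean bias
  must stay below max(0.03, 2 MC SE) — the slope/quadratic effects have
  per-replicate sampling SDs of 0.4–0.7 at this N, so an absolute 0.03 band
  alone would be dominated by Monte-Carlo noise — and the sandwich 95% CI of
  the arm-slope effect must cover in 92–97.5% of replicates.
- Diggle-Kenward: 60 replicates at N = 1000 with concurrent-outcome slope
  0.3; the mean estimate must sit within 2 MC SEs of 0.3, and the naive MAR
  fit must underestimate the t4 mean in at least 90% of replicates.
- Wu-Carroll: 40 replicates at N = 1000 with latent-intercept coefficient
  0.12, recovered within 2 MC SEs (9 quadrature nodes per dimension — the
  integration is exact-dimensional in the linear predictor, where 9 nodes are
  ample).
- Shape selection: 50 replicates of a pronounced early-decline-plus-rebound
  trajectory (α = (3.5, −3, 2), a classic relapse shape) at N = 1646; BIC
  must choose the quadratic shape in at least 90%. The trial-emulation
  defaults themselves interpolate a much gentler printed trajectory whose
  curvature is below BIC detectability at this N — a deliberate distinction
  between "emulate the study's marginals" and "a genuine quadratic trend".

Replicate counts are package choices balancing Monte-Carlo error against a
single-CPU run of the whole suite; the comparisons always use the honest MC
error of the sizes actually run.

## Known limitations

- Continuous-outcome models only; counts or ordinal outcomes are out of
  scope.
- The MNAR models are identified by untestable assumptions (outcome
  normality for the selection model, factor normality for the
  shared-parameter model, identifying restrictions for pattern mixtures);
  agreement across them does not prove MAR.
- Class proportions are treated as known in pattern-mixture SEs; the
  multinomial sampling uncertainty of the proportions is ignored (bootstrap
  option provided).
- The degenerate-ridge guard in `fit_wc` is a principled but heuristic
  convergence rule; a fit that triggers it reports a reduced selection
  regression and says so in `extra["dropped_factors"]`.
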