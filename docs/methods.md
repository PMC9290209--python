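# Methods

## The estimand and the simulation design

The object of study is the sampling behaviour of the pooled maximum
likelihood estimates of a multivariable logistic regression — the log-odds
of one-year mortality on ten baseline covariates — when one covariate is
missing at random (MAR) for a fraction `p_missing` of subjects and is
multiply imputed. Performance is judged against the "true" coefficient
vector θ, defined operationally as the logistic MLE in a very large
synthetic super-population with no missing data. Working with a
super-population rather than with the model's generating coefficients has
two advantages: the truth incorporates whatever distortion dichotomisation
and finite-population fitting introduce, and the missingness prevalence can
be fixed exactly by calibration before any sample is drawn.

## Data-generating process

1. **Covariates.** Ten latent variables from a multivariate normal with
   configurable mean vector and covariance. The first five columns are
   kept continuous (age in years, systolic blood pressure in mmHg, heart
   rate in bpm, hemoglobin in g/L, cholesterol in mmol/L). The last five
   are dichotomised at the *empirical* (1 − π) quantile of the realised
   column, so the sample prevalence of the 1-coded level equals its target
   π by construction (up to the 1/n granularity of the quantile): targets
   36/32/27/24/33% for female sex, angina, diabetes, previous AMI and
   current smoker. Theoretical normal quantiles would differ only by
   sampling noise; the empirical choice makes the prevalence check exact
   rather than statistical.
2. **Outcome.** Bernoulli with probability expit(β₀ + xᵀβ). The shipped
   slope vector is fixed; the intercept is recalibrated on the realised
   covariates (monotone bisection, tolerance 1e-4) so the expected event
   rate hits the configured target of 20.1%.
3. **Truth.** θ is the IRLS logistic MLE of the simulated outcome on the
   ten covariates in the full population (relative log-likelihood
   tolerance 1e-10, cap 100 iterations; non-convergence at population
   scale is a hard error because it indicates a broken configuration).
4. **Missingness.** A logistic missing-data model whose linear predictor
   uses the nine *other* covariates plus the outcome — the target variable
   has no coefficient slot at all, which makes the mechanism MAR
   structurally rather than by convention. Its intercept γ₀ is calibrated
   by the same bisection so that the population mean missingness
   probability equals `p_missing` (expected, not realised, proportion;
   the realised Bernoulli draw then differs only by binomial noise,
   ~±0.0005 at n = 10⁶). Bisection over γ₀ ∈ [−30, 30] is guaranteed to
   converge because the mean probability is strictly increasing in γ₀.
   Subjects with indicator 1 have the target set missing once, in the
   population, before any sampling.

### The shipped default constants

The registry estimates the design mimics are not public, so the defaults
in `misim.defaults` are this package's own stand-in, chosen on clinical
plausibility (means/SDs such as age 66 ± 13, cholesterol 4.9 ± 1.2;
modest signed correlations; adjusted log-odds such as +0.05/yr age,
−0.25/mmol/L cholesterol, +0.40 diabetes) with three sets of free
constants calibrated once to published summary statistics:

* dichotomisation thresholds → prevalences 36/32/27/24/33%;
* outcome intercept → event rate 20.1%;
* a single scale factor (0.846) on each missing-data slope vector → the
  missing-data models discriminate at c ≈ 0.67 (cholesterol model,
  evaluated at its observed 40.5% missingness) and c ≈ 0.71 (smoker
  model, at 13.4%).

With the c-statistics matched, the **Nagelkerke** generalized R² of the
two models comes out at ≈ 0.11–0.12 without further tuning, matching the
documented pair, whereas the Cox–Snell index gives 0.08/0.07. The two
published summaries are mutually consistent only under the Nagelkerke
index, so that is the index the calibration targets;
`model_diagnostics` computes Cox–Snell 1 − exp(−LR/n) by default and
Nagelkerke on request. Consequence of all this: population-level
calibration checks (prevalences, event rate, band limits, M rule) are
quantitative, while per-scenario bias/SE/coverage magnitudes are
qualitative reproductions of the design — they depend on the unpublished
coefficient values, and users with better information can supply every
constant via `DGPParams` or the YAML config.

## Imputation methods

All three methods are univariate (exactly one variable is incomplete),
use the nine complete covariates plus the analysis outcome as predictors,
and are *proper* in Rubin's sense (parameter uncertainty is drawn, not
plugged in). Observed values are never modified.

* **norm** — Bayesian linear regression: σ²⋆ = RSS/χ²(n_obs − p),
  β⋆ ~ N(β̂, σ²⋆(XᵀX)⁻¹) via the QR factor, imputations xβ⋆ + σ⋆z.
* **pmm** — Type-1 predictive mean matching: donor predictions use β̂,
  recipient predictions use β⋆; the donor pool is the k = 5 donors
  nearest in predicted value, one drawn uniformly; distance ties are
  broken uniformly at random (implemented as an infinitesimal uniform
  jitter, 1e-10 of the prediction scale, too small to reorder distinct
  distances). Imputed values are always members of the observed multiset.
* **logreg** — logistic MLE on the observed rows, β⋆ ~ N(β̂, I(β̂)⁻¹),
  imputations Bernoulli(expit(xβ⋆)). If the observed information is
  singular (separation), the draw degenerates to β̂ and the imputation is
  flagged.

`M` follows the percentage rule round(100·p_missing), floored at 2
(half-away-from-zero rounding; the rule's source is silent on non-integer
percentages).

## Fitting, pooling, intervals

The analysis model is fit by a package-authored IRLS Newton iteration
with step-halving (monotone in the log-likelihood), relative-likelihood
tolerance 1e-10, iteration cap 100, SEs from the inverse observed
information. The fitter never raises on separation — it returns the
capped, possibly enormous, estimate with a convergence flag. This is a
design requirement, not a shortcut: at 90–95% missingness a handful of
separated imputation-model or analysis-model fits per replicate is
expected, and *pooling* those erratic estimates is precisely what
produces the SE explosion the simulation exists to measure. Flagged fits
are therefore counted, never dropped (a `drop_flagged` sensitivity switch
exists in the summariser, and a ridge penalty — default 0 — is available
for users who want stabilised fits). A replicate fails outright only when
no estimate exists at all (e.g. one-class observed target, or a NaN total
variance from an exactly singular information matrix); such replicates
are recorded with a reason and excluded-but-counted in the metrics.

Pooling is Rubin's Rules (B with divisor M − 1); intervals are always
t-intervals on the Barnard–Rubin degrees of freedom (never the normal or
the old (M−1)/λ² rule alone), with ν = ν_obs in the B = 0 limit.

## Performance metrics

Per (scenario, term) over R usable replicates: mean estimate; relative
bias 100·(mean − θ)/θ (reported as missing, with absolute bias, when
θ = 0 — near-zero truths make the ratio unstable); empirical SD (divisor
R − 1); mean pooled SE; SE ratio (mean SE / empirical SD, the SE
calibration target of 1); MSE with divisor R (the identity
MSE = bias² + (R−1)/R·variance is asserted to 1e-10 in every cell); and
coverage in percent against the band
100·(0.95 ± 1.96·√(0.95·0.05/R)) — (93.65, 96.35) at R = 1,000.

## Determinism and problem sizes

A single master seed spawns every stream through
`numpy.random.SeedSequence` keyed by integer tags: population, outcome
and missingness draws, and per replicate one stream for the sample draw
and one for the imputation, keyed by (scenario key, replicate index). Any
replicate is thus reproducible in isolation, and serial and parallel
execution emit identical output.

The shipped drivers run a desk profile chosen to make the full
loop — population build, replicate sweep, metrics — comfortable on one
workstation core: populations of 10⁵–4×10⁵ for tests and exploratory
runs (10⁶, the study scale, in the acceptance script and available
everywhere via `n_pop`), 100–250 replicates instead of 1,000, and the
benign/stress scenario pairs instead of the full 258-scenario grid
(`default_grid()` constructs the full grid: three method arms ×
{500, 1,000, 5,000, 10,000} × 19 missingness levels plus 25,000 × 10).
Monte Carlo bands widen accordingly (92.3–97.7% at 250 replicates) and
are always computed from the replicate count actually used.

## What the generator does and does not emulate

It reproduces the *structure* of the motivating registry — covariate
count and types, realistic scales and correlations, event rate, MAR
models with the documented discrimination — and the exact experimental
protocol (without-replacement sampling, percentage-M rule, donor pool 5,
Barnard–Rubin intervals). It does not reproduce: the actual registry
joint distribution (normality of the latents and linear/additive
log-odds are assumptions; the real data's skewness, nonlinearities and
higher-order interactions are absent), multivariate missingness patterns
(eight simultaneously incomplete variables in the registry vs exactly one
here), MNAR mechanisms, or imputation-model mis-specification — all
deliberately out of scope. Passing tests therefore demonstrate the
statistical validity of the MI machinery under a correctly specified
model, not robustness on real registry data.

## Known limitations

* Per-scenario performance magnitudes (e.g. how large PMM's attenuation
  of the incomplete covariate's coefficient is at 85% missingness) are
  sensitive to the unpublished generating coefficients; with the shipped
  defaults the PMM bias at 85% missingness is small — within Monte Carlo
  noise of zero at desk-scale replicate counts (see the stress driver's
  output) — rather than the large attenuation a sharper covariate-target
  confounding structure would produce.
* At 95% missingness with n = 500 a few percent of replicates can fail
  outright (singular information in every-dataset fits); they are
  reported as failed rather than silently dropped or retried.
* The c/R² calibration of the missing-data models is evaluated at the
  registry missingness rates (40.5% / 13.4%); at other `p_missing` values
  only the intercept changes, so discrimination stays similar but R²
  varies with prevalence.
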