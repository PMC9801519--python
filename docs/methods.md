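# Methods

## Model and averaging

The analysis treats right-eye logarithmic visual acuity as a continuous
response in a normal linear model. For a subset γ of the s candidate
covariates,

    y = α + X_γ β_γ + ε,    ε ~ N(0, σ² I),

the intercept α belongs to every model and never counts toward model
size. The model space is the 2^s subsets, with a uniform prior over
models.

The coefficient prior is a Zellner g prior on the included block,
β_γ | σ² ~ N(0, g σ² (X_γ'X_γ)⁻¹), combined with improper flat priors on α
and log σ. This is the only standard prior family that yields a
closed-form marginal likelihood for every model, which is what makes
full enumeration practical. All fitting happens on mean-centered data,
which orthogonalises the intercept away; the centering report retains
the raw means so results can be restated on questionnaire scales.

With TSS = y'y (centered) and SS = TSS·(1 + g(1−R²_γ))/(1+g), the
marginal likelihood including all constants is

    log P(y|M_γ) = ln Γ((n−1)/2) − ((n−1)/2) ln 2π − ½ ln n
                   − (k/2) ln(1+g) − ((n−1)/2) ln(SS/2),

which reduces, up to a model-independent constant, to
(n−1−k)/2 · ln(1+g) − (n−1)/2 · ln(1+g(1−R²_γ)). Keeping the constants
lets the unit tests compare it directly against numerical integration of
likelihood × prior on tiny tables.

Conditional on a model, each included coefficient has a Student-t
posterior with n−1 degrees of freedom, location g/(1+g) times the OLS
estimate (the shrinkage identity tested against statsmodels) and scale²
= g/(1+g) · (X_γ'X_γ)⁻¹_jj · SS/(n−1). Averaged summaries:

* PIP_j = Σ_{γ ∋ j} P(M_γ|y);
* post mean_j = Σ_γ P(M_γ|y) · E[β_j | M_γ] with 0 where j is excluded;
* post SD_j by the law of total variance,
  Σ P(M|y)(Var + mean²) − (post mean)². The narrower
  within-model-only average (which omits the between-model dispersion of
  conditional means and therefore understates uncertainty) is available
  behind `within_model_variance_only=True` for comparability with
  reports that use it;
* sign consistency_j = Σ_{γ ∋ j} P(M_γ|y)·P(sign β_j = sign post mean_j |
  M_γ, y)/PIP_j from the conditional t posteriors, defined as 1.0 for a
  covariate included in no model. It reads as sign-robustness of the
  effect direction across models.

All model-probability arithmetic is in log space with log-sum-exp; ties
in model ranking break by enumeration order (size, then lexicographic).

## Evidence grades

PIP bands at 0.5 / 0.75 / 0.95 give four grades — none, weak, positive,
strong — with left-closed intervals (0.5 is weak, 0.75 positive, 0.95
strong), following the usual posterior-probability grading for BMA
variable selection. Some applied write-ups collapse the top two bands
into one "strong" label; the four-level scheme is finer and the
thresholds are configurable.

## MC3 sampler

The Markov-chain Monte Carlo model-composition sampler runs
Metropolis–Hastings on the inclusion hypercube: propose flipping one
uniformly chosen covariate in or out (a symmetric proposal), accept with
min(1, marginal-likelihood ratio). Defaults: 100 000 iterations, 10 000
burn-in. Estimates are raw post-burn-in visit frequencies — the same
estimator reported alongside exact probabilities in standard BMA
software — not likelihood re-weighted ones, so agreement with the exact
posterior is a genuine mixing diagnostic. Marginal likelihoods are
memoised by inclusion pattern (revisits dominate), and the proposal and
acceptance streams are pre-drawn from a seeded generator, making traces
bit-reproducible. Convergence reporting: total-variation distance and
correlation against the exact posterior when the space is enumerable,
split-half frequency correlation otherwise. On 32-model stage scenarios
the TV distance at default settings is typically 0.003–0.009; single-bit
MC3 mixes easily at s = 5.

Exact enumeration is capped at s = 25 (2^25 ≈ 3.4·10⁷ closed-form fits);
beyond it the pipeline runs sampler-only and averages over visited
models, which is an approximation that inherits Monte Carlo error.

## Synthetic stage scenarios

The generator emulates the three school-stage cohorts the analysis
targets. Covariates are drawn independently: no covariate covariance
information is available for calibration, and independence is the
conservative default for selection experiments. Weekly exercise is a
rounded, clipped 0–7 count; because rounding inflates variance by about
1/12 (Sheppard's correction), the draw uses sd' = sqrt(sd² − 1/12) so the
rounded sample lands on the target spread. Scores are normal draws
clipped at their scale floor; at the calibrated means/SDs clipping is
negligible. The outcome is α + Xβ + N(0, σ²) noise.

Preset calibration (means/SDs per stage, sample sizes 8457/8191/5901,
outcome noise 0.565–0.61, junior exercise effect 0.0177 and senior
0.0196 acuity units per day) reproduces the surveyed cohorts'
descriptive moments. The primary-stage preset has all true coefficients
zero (its survey analysis found no selectable variable) and uses a sleep
score in place of the mental-stress scale, which that age group did not
complete. Intercepts are set so outcome means land on the cohort means
given the covariate means: 4.79 primary, 4.60 junior, 4.42 senior.

Two stress presets support the simulation studies:

* `strong_single` — one true coefficient of 0.03 at n = 8191, noise SD
  0.61. The effect is placed on the mental-stress score (SD 8.68). A
  power calculation fixes this choice: 0.03 on a unit-SD covariate gives
  an expected |t| ≈ 4.5, for which the unit-information posterior
  reaches PIP ≥ 0.95 only ~74% of the time — not a *strong* single
  effect. On the 8.68-SD score the expected |t| ≈ 38, so the scenario
  genuinely stresses recovery rather than power.
* `pure_null` — all coefficients zero at n = 2000, for false-evidence
  calibration. Under the unit-information prior the chance that any of
  the five PIPs reaches 0.75 on pure noise is below 1% per replicate.

What the generator does **not** emulate: the stratified cluster sampling
design (rows are i.i.d.; design effects are ignored), covariate
correlation (optional nowhere; the presets are independent),
item-level questionnaire structure, and left/right-eye correlation.
Passing tests therefore show the inferential machinery is correct under
the stated linear model, not that the survey's design-based standard
errors are reproduced.

## Numerical choices and degenerate inputs

* Complete-case analysis: rows with any missing value are dropped before
  table construction and the count is reported.
* Constant covariate columns are rejected by name, not silently dropped;
  tables must keep n > s + 2 so the full model retains residual degrees
  of freedom.
* Exactly collinear columns inside a model raise a singular-model error
  (condition-number guard plus Cholesky failure). A consequence: a table
  with duplicated covariate columns cannot be enumerated, because every
  model containing both copies is singular — deduplicate first.
* R² is clamped to [0, 1] against round-off; PIPs are clamped the same
  way after accumulation.
* Report CSVs are written with 17-significant-digit floats so re-reading
  (with pandas' round-trip parser) reproduces values exactly, and re-runs
  are byte-identical; timing information goes to stderr only.

## Problem sizes used in the checks

The shipped verification suites run exact BMA on the full-size stage
scenarios (s = 5, n up to 8457; 32 closed-form fits each, fractions of a
second), a 25-replicate recovery study of `strong_single`, a
200-replicate false-evidence study of `pure_null`, a 100 000-iteration
MC3 run against the enumerated posterior, brute-force and quadrature
oracles on tables of up to 40 and 10 rows respectively, and the
shrinkage identity on 100 random tables.

## Known limitations

* The g-prior family is the only coefficient prior offered; mixtures of
  g priors (hyper-g, Zellner–Siow) are out of scope.
* The response is modelled as continuous; ordinal or logistic endpoints
  (e.g. myopia prevalence) are not supported.
* The Lindley/Bartlett effect is inherent: very large fixed g drives all
  posterior mass to the null model regardless of the data, so fixed-g
  analyses should report their g (the default ties g to n).
* Sampler-only mode (s > 25) reports frequency-based approximations for
  all averaged quantities; no bound on that approximation error is
  computed beyond the split-half diagnostic.
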