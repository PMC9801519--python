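# bma-vision

Bayesian model averaging (BMA) for selecting behavioural risk factors of
schoolchildren's eyesight from survey tables.

## The problem

School-health surveys record a continuous vision outcome — right-eye
logarithmic visual acuity on the Chinese 5-point decimal scale (about
4.0–5.3) — together with a handful of candidate covariates: weekly
exercise days, diet score, school-bullying score, mental-stress or sleep
score, internet-use score. Picking a single regression model and reading
its p-values understates uncertainty, because the choice of model is
itself uncertain. BMA removes that step: with s candidate covariates
there are K = 2^s linear models

    y = α + X_γ β_γ + ε,    ε ~ N(0, σ² I),

one per covariate subset γ, and every reported quantity is averaged over
all of them with posterior model probabilities as weights.

## The method

Each model gets a Zellner g prior on its coefficients,
β_γ | σ² ~ N(0, g σ² (X_γ'X_γ)⁻¹), with flat priors on the intercept and
log σ and a uniform prior over models. On mean-centered data this gives
the closed-form marginal likelihood

    log P(y | M_γ) = const + (n−1−k)/2 · log(1+g) − (n−1)/2 · log(1 + g(1−R²_γ)),

with k = |γ| and R²_γ the in-model coefficient of determination. From the
posterior model probabilities P(M_γ | y) ∝ P(y | M_γ) the package reports,
per covariate j:

* **PIP** — posterior inclusion probability, Σ over models containing j;
* **post mean / post SD** — model-averaged coefficient mean, and spread by
  the law of total variance (within-model variance plus between-model
  dispersion of conditional means);
* **sign consistency** — probability, conditional on inclusion, that the
  coefficient's sign agrees with the averaged mean;
* an **evidence grade** from the PIP bands 0.5 / 0.75 / 0.95
  (none / weak / positive / strong).

Exact enumeration covers s ≤ 25; an MC3 sampler (Metropolis–Hastings with
single add/remove moves on the inclusion pattern) cross-checks the exact
probabilities and extends beyond the cap. Because the surveyed cohort
data are restricted, a calibrated synthetic generator reproduces the
per-stage covariate and outcome moments (primary n=8457, junior n=8191,
senior n=5901) so the whole pipeline is testable end to end.

## Worked example

```python
from bma_vision import generate, get_scenario, run_bma

table = generate(get_scenario("junior_paper", seed=7))  # n=8191, s=5
result = run_bma(table)   # unit-information g prior, g = n
```

Printing the summary (see `examples/02_exact_bma.py`) gives:

```
variable        PIP  post mean   post SD   sign  grade
exercise     0.9927    0.02929   0.00722  1.000  strong
bullying     0.0131    0.00004   0.00066  0.726  none
network      0.0128   -0.00004   0.00079  0.714  none
m_stress     0.0125    0.00001   0.00010  0.697  none
diet         0.0109   -0.00000   0.00050  0.517  none
```

Exercise appears in models carrying 99.3% of the posterior mass — strong
evidence it affects acuity in this simulated junior cohort — with a
model-averaged effect of +0.029 acuity units per weekly exercise day;
every other covariate stays far below the 0.5 evidence floor. The other
scripts in `examples/` demonstrate the generator's calibration, the
MC3-vs-exact cross-check, and the three-stage CSV report driver. The
same analysis runs from a shell:

```bash
bma-vision simulate --preset junior_paper --seed 7 --out junior.csv
bma-vision run --input junior.csv --outcome acuity --sampler on --seed 7 --out report/
```

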