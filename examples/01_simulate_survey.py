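"""Generate one synthetic junior-stage survey table and check its calibration.

The generator draws weekly-exercise days as a discretised 0-7 count and
the questionnaire scores as truncated normals, then builds the acuity
outcome from the stage's linear model. The printed moments should land
on the cohort targets (exercise 2.72 +/- 1.01 days, acuity spread ~0.61).
"""

from bma_vision import generate, get_scenario

scenario = get_scenario("junior_paper", seed=7)
table = generate(scenario)

print(f"stage={table.stage_label}  n={table.n}  covariates={', '.join(table.names)}")
print(f"{'variable':<10} {'target mean':>11} {'sample mean':>11} "
      f"{'target sd':>9} {'sample sd':>9}")
for j, spec in enumerate(scenario.covariate_specs):
    col = table.covariates[:, j]
    print(f"{spec.name:<10} {spec.mean:>11.2f} {col.mean():>11.2f} "
          f"{spec.sd:>9.2f} {col.std():>9.2f}")
print(f"outcome mean {table.outcome.mean():.3f}, sd {table.outcome.std():.3f} "
      "(logarithmic acuity, 5-point decimal scale)")
print("Sample moments within sampling error of the targets confirm the "
      "generator reproduces the cohort's descriptive statistics.")
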