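"""Cross-check exact posterior model probabilities with the MC3 sampler.

MC3 walks the inclusion hypercube by single add/remove moves; its visit
frequencies estimate the same posterior the enumeration computes
exactly. Agreement (small total-variation distance, correlation ~1)
validates both routes.
"""

import numpy as np

from bma_vision import (
    PriorSettings,
    SamplerSettings,
    convergence_report,
    enumerate_models,
    fit_all_models,
    generate,
    get_scenario,
    mc3_run,
    posterior_model_probs,
    validate_and_center,
)

table = generate(get_scenario("junior_paper", seed=7))
centered, _ = validate_and_center(table)
prior = PriorSettings()

models = enumerate_models(table.s)
exact = posterior_model_probs(fit_all_models(centered, models, prior))

trace = mc3_run(centered, prior, SamplerSettings(n_iter=100_000, burn_in=10_000, seed=7))
freq = trace.pmp_vector(models)
report = convergence_report(trace, models, exact)

top = np.argsort(-exact)[:3]
print(f"{'model':<28} {'PMP (exact)':>12} {'PMP (MCMC)':>12}")
for idx in top:
    label = "{" + ", ".join(table.names[j] for j in models[idx].included) + "}"
    print(f"{label or '{}':<28} {exact[idx]:>12.5f} {freq[idx]:>12.5f}")
print(f"acceptance rate {trace.acceptance_rate:.3f}, "
      f"TV distance {report['tv_distance']:.4f}, "
      f"correlation {report['correlation']:.5f}")
print("TV distance well below 0.01 means the sampled and exact model "
      "probabilities are interchangeable at reporting precision.")
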