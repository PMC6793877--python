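"""Simulate a cohort and recover its generating parameters by MLE.

Generates 20 synthetic subjects choosing per the hybrid effort model at
the published median parameters, fits the model back to each subject's
363 choices, and compares the recovered medians with the generating truth.
"""

import effortchoice as ec

grid = ec.build_effort_grid(n_repetitions=3, rng_seed=1)
hybrid = ec.get_model("loss_aversion_encoding")
truth = {"lam": 0.71, "gamma": 1.61, "mu": 0.064}

spec = ec.CohortSpec(n_subjects=20, task="EFF", generating_model=hybrid,
                     param_distribution=truth, design=grid, seed=1)
choices, ground_truth = ec.generate_cohort(spec)
print(f"simulated {len(choices)} choices; "
      f"overall acceptance rate {choices.response.mean():.3f}")

fits = ec.fit_cohort(choices, [hybrid], n_restarts=20, seed=2)
for p in ("lam", "gamma", "mu"):
    print(f"  {p:5s}: generating {truth[p]:<6g} recovered median {fits[p].median():.3f}")

# lam < 1 is relief-seeking (reductions in effort valued relatively more),
# gamma > 1 is increasing sensitivity to absolute effort; their recovery
# within the published interquartile ranges validates the estimator.
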