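"""Descriptive choice statistics: rejection matrices and monotone trends.

Tabulates how often simulated subjects reject lotteries across the
gain × loss grid, and tests (Mann-Kendall) that rejection increases with
the potential loss and decreases with the potential gain.
"""

import effortchoice as ec

grid = ec.build_effort_grid(n_repetitions=3, rng_seed=6)
hybrid = ec.get_model("loss_aversion_encoding")
spec = ec.CohortSpec(20, "EFF", hybrid,
                     {"lam": 0.71, "gamma": 1.61, "mu": 0.064}, grid, seed=6)
choices, _ = ec.generate_cohort(spec)

rej = ec.rejection_matrix(choices)
print("rejection frequency vs loss level (gains averaged out):")
print(rej.loss_marginal.round(2).to_string())

loss_trend = ec.mann_kendall_trend(rej.loss_marginal.to_numpy())
gain_trend = ec.mann_kendall_trend(rej.gain_marginal.to_numpy())
print(f"\nMann-Kendall vs loss:  S = {loss_trend.s:+d}, p = {loss_trend.p_value:.2e}")
print(f"Mann-Kendall vs gain axis (-100%..0%): S = {gain_trend.s:+d}, "
      f"p = {gain_trend.p_value:.2e}")

ratio = ec.loss_gain_ratio({"lam": 0.71, "gamma": 1.61, "mu": 0.064}, hybrid)
print(f"\nloss/gain valuation ratio at the generating parameters: {ratio:.2f}")

# S = +55 would be a perfectly monotone increase over the 11 loss levels;
# a significant positive S along both axes reproduces the behavioural
# signature of effort-lottery choices.
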