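"""Build the effort lottery grid and inspect a model's valuation of it.

The effort task offers 50:50 gambles between reaching against less
resistance (a gain) and more resistance (a loss), relative to a reference
of 35 N·s/m.  This script builds the 363-trial design, then shows how the
hybrid model (linear loss aversion on a power-transformed effort scale)
values a few example lotteries.
"""

import effortchoice as ec

grid = ec.build_effort_grid(n_repetitions=3, rng_seed=0)
print(f"design: {len(grid)} trials, "
      f"{grid[['gain_pct', 'loss_pct']].drop_duplicates().shape[0]} unique lotteries")
print(f"resistance range: b_gain {grid.b_gain.min()}-{grid.b_gain.max()} N·s/m, "
      f"b_loss {grid.b_loss.min()}-{grid.b_loss.max()} N·s/m")

hybrid = ec.get_model("loss_aversion_encoding")
params = {"lam": 0.71, "gamma": 1.61, "mu": 0.064}  # published EFF medians
print("\nlottery utilities under the hybrid model at the published medians:")
for gain_pct, loss_pct in [(-100, 100), (-50, 30), (-10, 80), (0, 0)]:
    b_gain = ec.percent_to_b(gain_pct)
    b_loss = ec.percent_to_b(loss_pct)
    u = hybrid.lottery_utility(b_gain, b_loss, params)
    p = hybrid.accept_probability(b_gain, b_loss, params)
    print(f"  gain {-gain_pct:3d}% / loss {loss_pct:3d}%:  "
          f"U_lot = {u:9.2f}  P(accept) = {p:.3f}")

# U_lot > 0 means the gamble beats the sure reference reach; the logistic
# choice rule converts the utility difference into an acceptance probability.
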