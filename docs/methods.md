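# Methods

## Task and design

Subjects choose between a sure option (reaching against a reference
viscous resistance of b = 35 N·s/m, displayed as "0% more/less effort")
and a 50:50 lottery whose arms are a percentage *decrease* in effort
(gain, −100%…0%) and a percentage *increase* (loss, 0%…+100%), in 10%
steps. Displayed percentages map linearly to damping coefficients,
b = 35·(1 + pct/100), so the grid spans 0–70 N·s/m in 3.5 N·s/m steps and
the encoded gain/loss inputs span ±35 N·s/m around the reference. The full
design crosses 11 gain levels with 11 loss levels (121 unique lotteries,
including the degenerate 0%/0% gamble) and repeats each three times: 363
trials, order shuffled per subject by an explicit seed. The financial
analogue uses the same grid over $0–$100 gains and −$100–$0 losses.

## Candidate models

All models share the piecewise-power value function
SV(X) = X^α for X > 0, SV(X) = −λ(−X)^α for X < 0, the mixed-gamble
utility U_lot = ½SV(X⁺) + ½SV(X⁻), and the logistic acceptance rule
P = 1/(1 + exp(−μ(U_lot − U_sure))). They differ in the outcome encoding
and the free-parameter set:

| model | encoding | free parameters |
|---|---|---|
| symmetric (linear / quadratic) | X = Δb or Δ(b²) | λ, α, μ |
| no sensitivity (linear / quadratic) | X = Δb or Δ(b²) | λ, μ |
| no loss aversion (linear / quadratic) | X = Δb or Δ(b²) | μ |
| zero-effort reference | X = b^γ, all outcomes losses | γ, μ |
| loss aversion + encoding ("hybrid") | X = Δ(b^γ), α = 1 | λ, γ, μ |

The financial space drops the quadratic rows and adds a large-money
reference model (X = ($+100)^γ, all outcomes gains, sure bet 100^γ) and a
signed-power hybrid X = sign($)·|$|^γ — five models. Encodings are
transform-then-difference: the effort variable is first transformed, then
referenced against the transformed reference value, so X = 0 at the
reference for every Δ encoding and U_sure = 0 except for the two
non-reference-framed models. Powers of zero use the continuous extension
0^γ := 0 so the b = 0 and $0 arms are defined for all exponents.

Interpretation: λ > 1 is loss aversion, λ < 1 relief-seeking; γ > 1 means
increasing marginal sensitivity to absolute effort (steeper valuation of
high resistances); μ = 0 is random choice. Likelihoods are computed on raw
encoded units with no normalisation, so fitted μ values differ by orders
of magnitude between encodings (quadratic-encoding μ ≈ 0.003–0.012 against
linear-encoding μ ≈ 0.4–1); this is expected and harmless because μ only
ever multiplies that model's own utilities.

## Fitting

Per subject and model, parameters maximise the Bernoulli likelihood of
the accept/reject sequence; probabilities are clamped to [1e−12, 1−1e−12]
so the objective stays finite under deterministic parameter regions.
Bounds are 0–10 for α, λ, γ and 0–20 for μ, applied to every model, except
that the two money power-encoding models allow μ up to 1e5: when γ → 0
collapses the dollar scale toward 1, the maximum-likelihood μ inflates by
the inverse factor, and published fits for those models sit near 10⁴.

Optimisation is bounded Nelder-Mead (xatol = fatol = 1e−6, 2000 iterations
per start). The likelihood surface contains large exactly-flat plateaus —
wherever μ is steep enough that every choice probability clips, the
simplex sees a constant function and stalls — so starting points matter
more than polish. Each fit draws 50 random scan points per requested
restart (uniform in the bounds; μ log-uniform over [1e−5, bound] because
its scale, not its magnitude, is the unknown), ranks them by likelihood,
and starts half the Nelder-Mead runs from the best-ranked points and half
from fresh random draws; the best endpoint gets one polishing rerun. On
diagnostic cohorts this eliminated all cases where the fitted optimum was
worse than the generating parameters (5/20 subjects under plain uniform
restarts, including one miss by >4000 log-likelihood units). Trials are
aggregated to the 121 unique lotteries before evaluation, which makes one
likelihood evaluation a 121-point vector operation. Default 20 restarts;
fits are deterministic given (data, model, restarts, seed), and cohort
fitting derives per-cell seeds from the master seed so cells are
independent.

## Group-level model selection

Per-subject log model evidence is the AIC approximation −AIC/2 (only
evidence differences matter downstream). The random-effects scheme treats
each subject's generating model as drawn from unknown population
frequencies r with a flat Dirichlet prior (counts 1): a variational loop
alternates subject responsibilities g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα)) with
count updates α = α₀ + Σ_n g_n, to a 1e−8 tolerance (max 500 iterations).
Exceedance probabilities are estimated from 10⁵ seeded Dirichlet draws
(Monte-Carlo SE ≈ 0.0016 at p = 0.5). The Bayesian omnibus risk compares
the variational free energy of this model against the null that all
frequencies equal 1/K (whose exact evidence is Σ_n logsumexp(L_n) − N·log K):
BOR = 1/(1 + exp(F_rfx − F_null)). Protected exceedance probabilities
blend the two: pxp = (1 − BOR)·xp + BOR/K. The winner is the pxp argmax
(ties break to the lowest index and are flagged). For K = 2 and one
subject the exceedance probability has a Beta-tail closed form, used as an
independent check in the tests.

## Synthetic cohorts

The generator emulates the study conditions: each subject receives the
363-trial design in their own shuffled order and accepts each lottery by a
Bernoulli draw at the model's acceptance probability. Per-subject
parameters are either a point mass (used when reproducing a published
median row) or heterogeneous. Heterogeneous parameters are drawn from a
split log-normal — log-median at the published median, separate lower and
upper log-spreads chosen so that q1, median and q3 all match the published
values exactly. A symmetric log-normal was rejected because parameter fits
are strongly right-skewed (e.g. γ median 1.61, IQR 1.21–4.21) and matching
only the IQR ratio misplaces a large probability mass below the true lower
quartile, into the region where the hybrid model degenerates into its
nested linear special case. Draws are rejection-resampled into the fitting
bounds. Published quartiles printed as 0.00 are floored (μ at 0.005, γ at
0.001); such draws remain behaviourally near-degenerate, which is what a
zero quartile expresses.

Optional columns for schema completeness: a strong/weak choice label
(strong where |ΔU| exceeds its within-subject median) and a response time
decreasing noisily in |ΔU|. Neither is a model of real strength or RT
data and neither is used in fitting.

What passing tests on these cohorts do *not* show: real subjects exhibit
trial-order effects, lapses, and within-session drift that the generator
omits, and the published parameter distributions are summaries of 18–20
subjects, not population truths. Recovery results validate the estimator
and the selection machinery under the model's own assumptions, not the
model itself.

## Confusion (identifiability) analysis

For each generating model: draw 20 subjects from its parameter prior,
simulate choices, fit every candidate, run the random-effects selection,
record the winner; repeat over Monte-Carlo runs and tabulate the
generating × selected win-count matrix. The default prior is the
split log-normal anchored at each model's published median/IQR. A uniform
prior over the fitting bounds is available but not the default: uniform
λ, γ up to 10 makes most simulated subjects reject (or accept) everything,
data that every candidate fits at likelihood ≈ 1, so selection collapses
to the AIC parsimony rank rather than testing identifiability. Note that
identifiability of the hybrid model is intrinsically prior-dependent: at
γ = 1 or γ = 2 it coincides exactly with the linear or quadratic
two-parameter model, so cohorts drawn mostly near those points are
legitimately attributed to the nested model.

## Problem sizes and numerical choices

Acceptance-scale runs use 20 subjects × 363 trials, 20 restarts per fit,
10⁵ Dirichlet draws, and 3 Monte-Carlo confusion runs restricted to the
hybrid generating row — sizes chosen so a full pipeline pass completes in
minutes on one CPU while keeping every statistic at study scale.
Recovered λ/γ medians at the published generating values are accurate to
a few percent; individual subjects vary more because with small μ the
likelihood constrains (λ, γ) mainly through the decision boundary they
imply. Degenerate inputs are defined, not special-cased: the 0%/0%
lottery has utility 0 under every Δ encoding (acceptance probability ½),
constant sequences give a Mann-Kendall S of 0 with p = 1, and all-accept
data produce an all-zero rejection matrix.

## Delegations and limitations

Wilcoxon signed-rank, Shapiro-Wilk, Pearson correlation and paired t-tests
delegate to scipy.stats; the two-way repeated-measures ANOVA on
subjective values delegates to pingouin. The Mann-Kendall trend test is
implemented from its definition (S = Σ_{i<j} sign(x_j − x_i), tie-corrected
normal variance, continuity correction) because package conventions for
ties and approximations vary. Not implemented by design: response-time
models, probability weighting (outcome probabilities are objectively 0.5),
hierarchical/empirical-Bayes fitting, standard errors on per-subject point
estimates, and fixed-effects (summed Bayes factor) model comparison.
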