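"""Random-effects Bayesian model selection and model-confusion analysis.

Group-level model comparison treats the model identity as a random effect:
subjects are drawn from a population with unknown model frequencies r, with
a Dirichlet prior over r.  Given per-subject log model evidences (here the
AIC approximation, log p(y|m) ≈ −AIC/2), a variational scheme alternates
between per-subject model responsibilities and Dirichlet counts.  Reported
quantities:

* expected posterior model frequencies  E[r | y];
* exceedance probabilities xp_k = P(r_k > r_j ∀ j ≠ k | y), estimated by
  sampling the posterior Dirichlet;
* the Bayesian omnibus risk (BOR), the posterior probability of the null
  hypothesis that all models are equally frequent, from the free-energy
  comparison of the random-effects model against that null;
* protected exceedance probabilities pxp_k = (1 − BOR)·xp_k + BOR/K.

The confusion analysis closes the loop on identifiability: simulate
cohorts from each candidate model with parameters drawn from a prior, fit
every candidate to each cohort, run the group-level selection, and count
which model wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .fitting import FitResult, fit_cohort
from .models import ModelSpec


def log_evidence_from_aic(fit: FitResult | float) -> float:
    """AIC approximation to the log model evidence: −AIC/2."""
    aic = fit.aic if isinstance(fit, FitResult) else float(fit)
    return -0.5 * aic


def evidence_matrix(fits: pd.DataFrame, model_names: Sequence[str]) -> np.ndarray:
    """Pivot a tidy fit table into a subjects × models log-evidence matrix."""
    wide = fits.pivot(index="subject_id", columns="model", values="aic")
    return -0.5 * wide[list(model_names)].to_numpy(dtype=float)


@dataclass
class BMSResult:
    """Posterior summary of the random-effects model comparison."""

    model_names: list[str]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    n_subjects: int
    converged: bool
    n_iterations: int
    free_energy: float = field(default=np.nan)


def _dirichlet_log_norm(alpha: np.ndarray) -> float:
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum())


def rfx_bms(
    log_evidence: np.ndarray,
    model_names: Sequence[str] | None = None,
    prior_alpha: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_samples: int = 100_000,
    seed: int = 0,
) -> BMSResult:
    """Group-level random-effects model selection from log evidences.

    Parameters
    ----------
    log_evidence : (N subjects, K models) array of per-subject log model
        evidences (any per-subject additive constant cancels).
    prior_alpha : symmetric Dirichlet prior count per model (1 = flat).
    n_samples : Dirichlet draws for the exceedance-probability estimate.
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be an N × K matrix with K ≥ 2")
    if not np.isfinite(L).all():
        raise ValueError("log_evidence contains non-finite entries")
    n, k = L.shape
    names = list(model_names) if model_names is not None else [f"m{i}" for i in range(k)]

    alpha0 = np.full(k, float(prior_alpha))
    alpha = alpha0.copy()
    g = np.full((n, k), 1.0 / k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logu = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged and max_iter > 0:
        raise RuntimeError(f"rfx_bms failed to converge in {max_iter} iterations")

    expected = alpha / alpha.sum()

    # exceedance probabilities by posterior Dirichlet sampling
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    wins = np.bincount(np.argmax(draws, axis=1), minlength=k)
    xp = wins / wins.sum()

    # free energy of the RFX model (variational lower bound)
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_g = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    f_rfx = (
        float(np.sum(g * (L + e_ln_r)))
        + _dirichlet_log_norm(alpha0)
        - _dirichlet_log_norm(alpha)
        + float(np.dot(alpha0 - alpha, e_ln_r))
        + entropy_g
    )
    # evidence of the null: every subject's data from equal frequencies 1/K
    f_null = float(np.sum(logsumexp(L, axis=1) - np.log(k)))
    bor = float(1.0 / (1.0 + np.exp(f_rfx - f_null)))

    pxp = (1.0 - bor) * xp + bor / k
    return BMSResult(
        model_names=names,
        dirichlet_alpha=alpha,
        expected_freq=expected,
        xp=xp,
        pxp=pxp,
        bor=bor,
        n_subjects=n,
        converged=converged,
        n_iterations=it,
        free_energy=f_rfx,
    )


def select_winner(bms: BMSResult) -> dict:
    """Winning model = argmax protected exceedance probability.

    Exact ties break to the lowest index and are flagged in the report.
    """
    idx = int(np.argmax(bms.pxp))
    tie = bool(np.sum(bms.pxp == bms.pxp[idx]) > 1)
    return {
        "winner_index": idx,
        "winner": bms.model_names[idx],
        "pxp": float(bms.pxp[idx]),
        "bor": bms.bor,
        "tie": tie,
    }


# ---------------------------------------------------------------------------
# Confusion analysis
# ---------------------------------------------------------------------------

@dataclass
class ParamPrior:
    """Parameter prior for simulated cohorts in the confusion analysis.

    With ``model_dists`` set (a mapping model name → {param: distribution
    with a ``draw(rng)`` method}), parameters are drawn from those
    per-model distributions, rejection-resampled into the fitting bounds —
    this is the default, anchored at the published population fits (see
    :mod:`effortchoice.priors`).  Without it, each free parameter is drawn
    uniform over its fitting bounds except the inverse temperature mu,
    drawn log-uniform on [0.01, upper bound] so that simulated subjects are
    not all near-random choosers.  Custom per-parameter samplers (callables
    rng → float) override both.
    """

    mu_log_range: tuple[float, float] = (0.01, 20.0)
    model_dists: Mapping[str, Mapping[str, object]] | None = None
    custom: Mapping[str, Callable[[np.random.Generator], float]] = field(default_factory=dict)

    def sample(self, model: ModelSpec, rng: np.random.Generator) -> dict[str, float]:
        dists = (self.model_dists or {}).get(model.name)
        out: dict[str, float] = {}
        for name in model.free_params:
            lo, hi = model.bounds[name]
            if name in self.custom:
                out[name] = float(self.custom[name](rng))
            elif dists is not None:
                for _ in range(1000):
                    v = float(dists[name].draw(rng))
                    if lo <= v <= hi:
                        break
                else:
                    raise RuntimeError(f"could not draw {name} within [{lo}, {hi}]")
                out[name] = v
            elif name == "mu":
                lo_mu = max(self.mu_log_range[0], 1e-6)
                hi_mu = min(self.mu_log_range[1], hi)
                out[name] = float(np.exp(rng.uniform(np.log(lo_mu), np.log(hi_mu))))
            else:
                out[name] = float(rng.uniform(lo, hi))
        return out


@dataclass
class ConfusionResult:
    """Generating-model × selected-model win counts over Monte-Carlo runs."""

    matrix: pd.DataFrame
    runs: list[dict]

    def diagonal_rate(self, model_name: str) -> float:
        row = self.matrix.loc[model_name]
        return float(row[model_name] / row.sum())


def confusion_analysis(
    model_space: list[ModelSpec],
    design: pd.DataFrame,
    n_subjects: int = 20,
    n_mc: int = 8,
    prior: ParamPrior | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    generating_models: list[ModelSpec] | None = None,
) -> ConfusionResult:
    """Monte-Carlo identifiability check for a model space.

    For each generating model and each of ``n_mc`` runs: draw ``n_subjects``
    parameter sets from the prior, simulate choices on ``design``, fit every
    candidate, run the random-effects selection and record the winner.
    ``generating_models`` restricts the rows simulated (the full candidate
    space is always fit); by default every model generates.  The default
    prior is the published-population prior for the design's task.
    """
    from .cohort import simulate_choices  # local import to avoid a cycle

    if prior is None:
        from .priors import empirical_prior

        prior = empirical_prior(str(design["task"].iloc[0]))
    gens = generating_models if generating_models is not None else model_space
    names = [m.name for m in model_space]
    counts = pd.DataFrame(0, index=[m.name for m in gens], columns=names, dtype=int)
    runs: list[dict] = []
    for gi, gen in enumerate(gens):
        for mc in range(n_mc):
            run_seed = np.random.SeedSequence([int(seed), gi, mc]).generate_state(1)[0]
            rng = np.random.default_rng(int(run_seed))
            frames = []
            for s in range(n_subjects):
                params = prior.sample(gen, rng)
                ch = simulate_choices(params, gen, design, rng, subject_id=f"sim{s:02d}")
                frames.append(ch)
            data = pd.concat(frames, ignore_index=True)
            fits = fit_cohort(data, model_space, n_restarts=n_restarts, seed=int(run_seed))
            L = evidence_matrix(fits, names)
            bms = rfx_bms(L, model_names=names, seed=int(run_seed))
            win = select_winner(bms)
            counts.loc[gen.name, win["winner"]] += 1
            runs.append({
                "generating": gen.name,
                "mc_index": mc,
                "winner": win["winner"],
                "pxp": bms.pxp.tolist(),
                "bor": bms.bor,
            })
    return ConfusionResult(matrix=counts, runs=runs)
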