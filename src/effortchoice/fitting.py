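"""Per-subject maximum-likelihood estimation with multi-restart bounded search.

Each subject × model cell is fit by minimising the Bernoulli negative
log-likelihood with a bounded Nelder-Mead simplex, restarted from uniform
draws within the parameter bounds (log-uniform for an inverse temperature
whose upper bound is very large).  Trials are aggregated to unique
(gain, loss) cells before evaluation, which makes a 363-trial likelihood a
121-point computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .models import ModelSpec, P_EPS

#: Nelder-Mead convergence tolerances and iteration cap per restart.
XATOL = 1e-6
FATOL = 1e-6
MAXITER = 2000


def outcome_arrays(choices: pd.DataFrame, domain: str):
    """Extract (gain, loss, response) arrays in model-raw units.

    Effort models consume damping coefficients (taken from ``b_gain``/
    ``b_loss`` if present, else derived from the signed percent columns);
    money models consume signed dollars.
    """
    if domain == "money":
        gain = choices["usd_gain"].to_numpy(dtype=float)
        loss = choices["usd_loss"].to_numpy(dtype=float)
    elif "b_gain" in choices.columns:
        gain = choices["b_gain"].to_numpy(dtype=float)
        loss = choices["b_loss"].to_numpy(dtype=float)
    else:
        gain = 35.0 * (1.0 + choices["gain_pct"].to_numpy(dtype=float) / 100.0)
        loss = 35.0 * (1.0 + choices["loss_pct"].to_numpy(dtype=float) / 100.0)
    resp = None
    if "response" in choices.columns:
        resp = choices["response"].to_numpy(dtype=float)
    return gain, loss, resp


def _aggregate(gain, loss, resp):
    """Collapse trials to unique (gain, loss) cells with accept/total counts."""
    pairs = np.column_stack([gain, loss])
    uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
    n_total = np.bincount(inv, minlength=len(uniq)).astype(float)
    n_accept = np.bincount(inv, weights=resp, minlength=len(uniq)).astype(float)
    return uniq[:, 0], uniq[:, 1], n_accept, n_total


@dataclass
class FitResult:
    """Best-of-restarts MLE output for one subject × model cell."""

    model_name: str
    params: dict[str, float]
    neg_ll: float
    aic: float
    n_params: int
    n_trials: int
    n_restarts: int
    best_restart_index: int
    converged: bool
    restart_neg_lls: list[float] = field(default_factory=list, repr=False)


def _make_objective(model: ModelSpec, choices: pd.DataFrame):
    gain, loss, resp = outcome_arrays(choices, model.domain)
    if resp is None:
        raise ValueError("choices table has no 'response' column")
    if len(resp) == 0:
        raise ValueError("empty choice list")
    if not np.isin(resp, (0.0, 1.0)).all():
        raise ValueError("responses must be 0 or 1")
    g, l, n_acc, n_tot = _aggregate(gain, loss, resp)

    def nll(theta) -> float:
        params = model.theta_to_params(theta)
        du = model.delta_utility(g, l, params)
        p = np.clip(expit(params["mu"] * du), P_EPS, 1.0 - P_EPS)
        return float(-np.sum(n_acc * np.log(p) + (n_tot - n_acc) * np.log1p(-p)))

    return nll, len(resp)


def _random_points(model: ModelSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Random parameter points: uniform per parameter, mu log-uniform.

    The inverse temperature's maximum-likelihood value varies over several
    orders of magnitude between encodings (raw utilities differ in scale),
    so its starts must cover scales, not just the interval.
    """
    pts = np.empty((n, model.n_params))
    for i, name in enumerate(model.free_params):
        lo, hi = model.bounds[name]
        if name == "mu":
            pts[:, i] = np.exp(rng.uniform(np.log(1e-5), np.log(hi), n))
        else:
            pts[:, i] = rng.uniform(lo, hi, n)
    return pts


#: Coarse likelihood-scan points evaluated per requested restart.
SCAN_PER_RESTART = 50


def fit_subject(
    choices: pd.DataFrame,
    model: ModelSpec,
    n_restarts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Fit one model to one subject's trials by multi-restart bounded MLE.

    The likelihood surface has large saturated plateaus (wherever mu is
    too steep every choice probability clips to 0/1), on which a simplex
    search stalls immediately.  Restart starting points are therefore
    chosen in two halves: the best-ranked points of a coarse random scan of
    the likelihood (50 points per restart), plus fresh random draws for
    basin diversity.  A Nelder-Mead run starts from each, and the best
    endpoint gets one polishing rerun.  Deterministic given
    (choices, model, n_restarts, seed); ``converged`` is False only if
    every run failed, in which case the best point found is still reported.
    """
    nll, n_trials = _make_objective(model, choices)
    rng = np.random.default_rng(seed)
    bounds = [model.bounds[p] for p in model.free_params]
    options = {"xatol": XATOL, "fatol": FATOL, "maxiter": MAXITER, "maxfev": 2 * MAXITER}

    scan = _random_points(model, rng, SCAN_PER_RESTART * n_restarts)
    scan_vals = np.array([nll(p) for p in scan])
    n_ranked = (n_restarts + 1) // 2
    starts = np.vstack([
        scan[np.argsort(scan_vals)[:n_ranked]],
        _random_points(model, rng, n_restarts - n_ranked),
    ])

    best = None
    best_idx = -1
    restart_nlls: list[float] = []
    any_ok = False
    for k, x0 in enumerate(starts):
        res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds, options=options)
        restart_nlls.append(float(res.fun))
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_idx = res, k
    polish = minimize(nll, best.x, method="Nelder-Mead", bounds=bounds, options=options)
    if polish.fun < best.fun:
        best = polish
        any_ok = any_ok or bool(polish.success)

    params = dict(zip(model.free_params, (float(v) for v in best.x)))
    neg_ll = float(best.fun)
    return FitResult(
        model_name=model.name,
        params=params,
        neg_ll=neg_ll,
        aic=2.0 * model.n_params + 2.0 * neg_ll,
        n_params=model.n_params,
        n_trials=n_trials,
        n_restarts=n_restarts,
        best_restart_index=best_idx,
        converged=any_ok,
        restart_neg_lls=restart_nlls,
    )


def fit_cohort(
    dataset: pd.DataFrame,
    model_space: list[ModelSpec],
    n_restarts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every model to every subject; one tidy row per (subject, model).

    Per-cell seeds are derived from the master seed and the subject/model
    position, so removing a model or a subject leaves the other cells'
    results unchanged.
    """
    subjects = sorted(dataset["subject_id"].unique())
    rows = []
    for si, subj in enumerate(subjects):
        sub = dataset[dataset["subject_id"] == subj]
        for mi, model in enumerate(model_space):
            cell_seed = np.random.SeedSequence([int(seed), si, mi]).generate_state(1)[0]
            fit = fit_subject(sub, model, n_restarts=n_restarts, seed=int(cell_seed))
            row = {
                "subject_id": subj,
                "model": model.name,
                "neg_ll": fit.neg_ll,
                "aic": fit.aic,
                "n_params": fit.n_params,
                "n_trials": fit.n_trials,
                "converged": fit.converged,
            }
            for pname, pval in fit.params.items():
                row[pname] = pval
            rows.append(row)
    return pd.DataFrame(rows)
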