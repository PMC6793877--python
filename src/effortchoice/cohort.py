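"""Synthetic subjects and trial-level choice data.

The study's raw choice data are not deposited, so analyses are exercised on
synthetic cohorts with the same structure: each subject sees the 121-lottery
× 3-repetition grid in a randomised order and accepts or rejects each
lottery with the logistic probability implied by their latent parameters.

Per-subject parameters are either a point mass (every subject at the given
values, as when reproducing a table row's medians) or heterogeneous,
log-normal around a median with spread chosen so the interquartile range
matches a target — the published tables report medians and IQRs only, and
the log-normal respects the positivity of all parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .fitting import outcome_arrays
from .models import ModelSpec

#: Normal quartile z, ties log-normal spread to a target IQR.
_Z_QUARTILE = 0.6744897501960817


@dataclass(frozen=True)
class ParamDist:
    """Distribution of one parameter across subjects.

    ``kind`` is "point" (everyone at ``median``) or "lognormal": a split
    log-normal centred at ``median`` whose lower and upper halves use
    separate spreads, sigma_low = ln(median/q1)/0.6745 and
    sigma_high = ln(q3/median)/0.6745, so all three published quantiles
    (q1, median, q3) are reproduced exactly — parameter fits are typically
    right-skewed and a symmetric log-normal cannot hit both quartiles.
    """

    kind: str
    median: float
    iqr: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("point", "lognormal"):
            raise ValueError("kind must be 'point' or 'lognormal'")
        if self.kind == "lognormal":
            if self.iqr is None or not (0 < self.iqr[0] <= self.iqr[1]):
                raise ValueError("lognormal requires a positive (q1, q3) IQR")
            if not self.iqr[0] <= self.median <= self.iqr[1]:
                raise ValueError("median must lie inside the IQR")
            if self.median <= 0:
                raise ValueError("lognormal requires a positive median")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return float(self.median)
        log_m = np.log(self.median)
        sigma_low = (log_m - np.log(self.iqr[0])) / _Z_QUARTILE
        sigma_high = (np.log(self.iqr[1]) - log_m) / _Z_QUARTILE
        z = abs(rng.normal())
        sigma = sigma_high if rng.random() < 0.5 else -sigma_low
        return float(np.exp(log_m + sigma * z))


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``param_distribution`` maps each of the generating model's free
    parameters to a :class:`ParamDist` (or a bare float, shorthand for a
    point mass).  Draws outside the fitting bounds are rejection-resampled.
    """

    n_subjects: int
    task: str
    generating_model: ModelSpec
    param_distribution: Mapping[str, ParamDist | float]
    design: pd.DataFrame
    seed: int = 0
    emit_strength: bool = False
    emit_rt: bool = False
    _max_resamples: int = field(default=1000, repr=False)


def _as_dist(d) -> ParamDist:
    return d if isinstance(d, ParamDist) else ParamDist("point", float(d))


def draw_subject_params(spec: CohortSpec, subject_index: int) -> dict[str, float]:
    """Draw one subject's generating parameters; reproducible per index."""
    seed = np.random.SeedSequence([int(spec.seed), int(subject_index)]).generate_state(1)[0]
    rng = np.random.default_rng(int(seed))
    model = spec.generating_model
    out: dict[str, float] = {}
    for name in model.free_params:
        dist = _as_dist(spec.param_distribution[name])
        lo, hi = model.bounds[name]
        for _ in range(spec._max_resamples):
            v = dist.draw(rng)
            if lo <= v <= hi:
                out[name] = v
                break
        else:
            raise RuntimeError(
                f"could not draw {name} within bounds [{lo}, {hi}] "
                f"after {spec._max_resamples} resamples"
            )
    return out


def simulate_choices(
    params: Mapping[str, float],
    model: ModelSpec,
    design: pd.DataFrame,
    rng: np.random.Generator,
    subject_id: str = "sim00",
    emit_strength: bool = False,
    emit_rt: bool = False,
) -> pd.DataFrame:
    """Bernoulli accept/reject draws for every trial of a design.

    The returned trial table keeps the design's order and columns and adds
    ``subject_id`` and ``response``; optionally a cosmetic ``strength``
    label (strong where |ΔU| exceeds its within-subject median) and a
    noisy response time decreasing in |ΔU| (schema completeness only — not
    a response-time model).
    """
    gain, loss, _ = outcome_arrays(design, model.domain)
    p = model.accept_probability(gain, loss, params)
    p = np.broadcast_to(np.asarray(p, dtype=float), gain.shape)
    out = design.copy()
    out.insert(0, "subject_id", subject_id)
    out["response"] = (rng.random(len(gain)) < p).astype(int)
    du = np.abs(model.delta_utility(gain, loss, params))
    if emit_strength:
        out["strength"] = np.where(du > np.median(du), "strong", "weak")
    if emit_rt:
        scale = np.median(du) + 1e-12
        base = 1200.0 + 1400.0 * np.exp(-du / scale)
        out["rt_ms"] = base * np.exp(rng.normal(0.0, 0.25, size=len(gain)))
    return out


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort's trial table and its ground-truth parameter table.

    Returns ``(choices, ground_truth)``: choices with one row per
    subject × trial, ground truth with one row per subject holding the
    latent generating parameters (for recovery scoring).
    """
    frames, truth = [], []
    for s in range(spec.n_subjects):
        params = draw_subject_params(spec, s)
        sim_seed = np.random.SeedSequence(
            [int(spec.seed), int(s), 941]).generate_state(1)[0]
        rng = np.random.default_rng(int(sim_seed))
        sid = f"sub{s:03d}"
        frames.append(
            simulate_choices(
                params,
                spec.generating_model,
                spec.design,
                rng,
                subject_id=sid,
                emit_strength=spec.emit_strength,
                emit_rt=spec.emit_rt,
            )
        )
        truth.append({"subject_id": sid, **params})
    return pd.concat(frames, ignore_index=True), pd.DataFrame(truth)
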