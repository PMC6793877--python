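"""Candidate prospect-theory models of effort and money valuation.

Every model shares the same skeleton.  A lottery outcome is first *encoded*
into a signed quantity X (effort reductions and dollar gains give X ≥ 0,
effort increases and dollar losses give X ≤ 0), then valued by the
piecewise-power prospect-theory value function

    SV(X) =  X**alpha            for X > 0
    SV(X) = -lam * (-X)**alpha   for X < 0

with value sensitivity ``alpha`` and loss-aversion coefficient ``lam``.
The utility of a 50:50 mixed gamble is U_lot = 0.5·SV(X⁺) + 0.5·SV(X⁻) and
the probability of accepting it over the sure (reference) outcome follows a
logistic rule with inverse temperature ``mu``:

    P(accept) = 1 / (1 + exp(-mu · (U_lot − U_sure)))

``mu = 0`` is random choice.  Candidate models differ in the encoding (the
transform of the damping coefficient b or the dollar amount, and the
reference it is measured against) and in which of alpha, lam, gamma and mu
are free.

Encodings
---------
``delta_linear``          X = −(b − 35): linear change in resistance.
``delta_quadratic``       X = −(b² − 35²): quadratic transform, then reference.
``delta_power``           X = −(b**gamma − 35**gamma): free-exponent transform
                          (the "loss aversion + encoding" hybrid).
``absolute_power``        X = b**gamma with every outcome a loss (no imposed
                          reference; the sure bet is −35**gamma).
``money_linear``          X = signed dollars.
``money_power_signed``    X = sign($)·|$|**gamma.
``money_translated_power`` X = ($ + 100)**gamma: all outcomes framed as gains
                          after translation; the sure bet is 100**gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

from .design import B_REFERENCE

#: Optimisation bounds shared by all standard models.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 10.0),
    "lam": (0.0, 10.0),
    "gamma": (0.0, 10.0),
    "mu": (0.0, 20.0),
}

#: Money power-encodings collapse the dollar scale when gamma → 0, which
#: inflates the fitted inverse temperature by orders of magnitude; their mu
#: bound is widened accordingly.
WIDE_MU_BOUNDS = dict(DEFAULT_BOUNDS, mu=(0.0, 1e5))

MONEY_TRANSLATION = 100.0

#: Probability floor for the Bernoulli log-likelihood.
P_EPS = 1e-12

ENCODING_KINDS = (
    "delta_linear",
    "delta_quadratic",
    "delta_power",
    "absolute_power",
    "money_linear",
    "money_power_signed",
    "money_translated_power",
)

_POWER_KINDS = ("delta_power", "absolute_power", "money_power_signed",
                "money_translated_power")


def _pow0(x, e):
    """x**e with the continuous extension 0**e := 0 (including e = 0)."""
    x = np.asarray(x, dtype=float)
    safe = np.where(x > 0.0, x, 1.0)
    return np.where(x > 0.0, np.power(safe, e), 0.0)


def encode_outcome(outcome, kind: str, gamma: float | None = None):
    """Encode a raw outcome (damping coefficient b, or signed dollars) as X.

    ``outcome`` is b in N·s/m for effort kinds and signed dollars for money
    kinds; scalars or arrays.  Power kinds require ``gamma``.
    """
    if kind not in ENCODING_KINDS:
        raise ValueError(f"unknown encoding kind {kind!r}")
    if kind in _POWER_KINDS and gamma is None:
        raise ValueError(f"encoding {kind!r} requires gamma")
    x = np.asarray(outcome, dtype=float)
    if kind == "delta_linear":
        out = -(x - B_REFERENCE)
    elif kind == "delta_quadratic":
        out = -(x**2 - B_REFERENCE**2)
    elif kind == "delta_power":
        out = -(_pow0(x, gamma) - B_REFERENCE**gamma)
    elif kind == "absolute_power":
        out = _pow0(x, gamma)
    elif kind == "money_linear":
        out = x
    elif kind == "money_power_signed":
        out = np.sign(x) * _pow0(np.abs(x), gamma)
    else:  # money_translated_power
        out = _pow0(x + MONEY_TRANSLATION, gamma)
    return out if out.ndim else float(out)


def subjective_value(X, alpha: float = 1.0, lam: float = 1.0):
    """Prospect-theory value function; SV(0) = 0, odd-symmetric at alpha = lam = 1."""
    if alpha < 0 or lam < 0:
        raise ValueError("alpha and lam must be non-negative")
    X = np.asarray(X, dtype=float)
    out = np.where(X >= 0.0, _pow0(X, alpha), -lam * _pow0(-X, alpha))
    return out if out.ndim else float(out)


def accept_probability(u_lot, u_sure, mu: float):
    """Logistic probability of accepting the lottery over the sure bet.

    P = 1 / (1 + exp(−mu·(U_lot − U_sure))); 0.5 at mu = 0 or indifference,
    numerically stable for arbitrarily large |mu·ΔU|.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    out = expit(mu * (np.asarray(u_lot, dtype=float) - np.asarray(u_sure, dtype=float)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate choice model: encoding kind plus free-parameter set.

    ``free_params`` is ordered (it is the optimisation vector layout);
    parameters absent from it take their value from ``fixed`` (default 1).
    """

    name: str
    kind: str
    free_params: tuple[str, ...]
    domain: str  # "effort" | "money"
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: DEFAULT_BOUNDS)

    def __post_init__(self):
        if self.kind not in ENCODING_KINDS:
            raise ValueError(f"unknown encoding kind {self.kind!r}")
        if self.domain not in ("effort", "money"):
            raise ValueError("domain must be 'effort' or 'money'")
        for p in self.free_params:
            if p not in ("alpha", "lam", "gamma", "mu"):
                raise ValueError(f"unknown parameter {p!r}")

    @property
    def n_params(self) -> int:
        return len(self.free_params)

    def full_params(self, params: Mapping[str, float]) -> dict[str, float]:
        """Merge free/fixed parameter values into a complete parameter dict."""
        out = {"alpha": 1.0, "lam": 1.0, "gamma": 1.0, "mu": 0.0}
        out.update(self.fixed)
        for p in self.free_params:
            out[p] = float(params[p])
        return out

    def theta_to_params(self, theta) -> dict[str, float]:
        return self.full_params(dict(zip(self.free_params, theta)))

    # -- valuation --------------------------------------------------------

    def arm_value(self, outcome_raw, params: Mapping[str, float]):
        """Subjective value of a single lottery arm (raw b or signed dollars)."""
        p = self.full_params(params)
        X = encode_outcome(outcome_raw, self.kind, p["gamma"])
        if self.kind == "absolute_power":
            # every outcome sits in the loss domain of the value function
            return -np.asarray(X, dtype=float)
        if self.kind == "money_translated_power":
            # every outcome framed as a gain; valued linearly on the encoding
            return np.asarray(X, dtype=float)
        return subjective_value(X, p["alpha"], p["lam"])

    def sure_bet_utility(self, params: Mapping[str, float]) -> float:
        """Utility of rejecting: the reference outcome under this model."""
        p = self.full_params(params)
        if self.kind == "absolute_power":
            return -float(B_REFERENCE ** p["gamma"])
        if self.kind == "money_translated_power":
            return float(MONEY_TRANSLATION ** p["gamma"])
        return 0.0

    def lottery_utility(self, gain_raw, loss_raw, params: Mapping[str, float]):
        """U_lot = 0.5·SV(gain arm) + 0.5·SV(loss arm)."""
        return 0.5 * self.arm_value(gain_raw, params) + 0.5 * self.arm_value(loss_raw, params)

    def delta_utility(self, gain_raw, loss_raw, params: Mapping[str, float]):
        return self.lottery_utility(gain_raw, loss_raw, params) - self.sure_bet_utility(params)

    def accept_probability(self, gain_raw, loss_raw, params: Mapping[str, float]):
        p = self.full_params(params)
        return accept_probability(
            self.lottery_utility(gain_raw, loss_raw, params),
            self.sure_bet_utility(params),
            p["mu"],
        )


def lottery_utility(gain_raw, loss_raw, model: ModelSpec, params) -> float:
    """Module-level convenience wrapper around :meth:`ModelSpec.lottery_utility`."""
    return model.lottery_utility(gain_raw, loss_raw, params)


def sure_bet_utility(model: ModelSpec, params) -> float:
    return model.sure_bet_utility(params)


def negative_log_likelihood(responses, probabilities) -> float:
    """Bernoulli negative log-likelihood of accept/reject responses.

    ``responses`` are 0/1 (1 = accept); probabilities are clamped to
    [1e−12, 1 − 1e−12] so the value stays finite under near-deterministic
    parameters.
    """
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ValueError("empty choice list")
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError("responses must be 0 (reject) or 1 (accept)")
    p = np.clip(np.asarray(probabilities, dtype=float), P_EPS, 1.0 - P_EPS)
    return float(-np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))


def model_nll(choices, model: ModelSpec, params) -> float:
    """Negative log-likelihood of a trial table under a model and parameters.

    ``choices`` is a DataFrame with the task's outcome columns and a
    ``response`` column.
    """
    from .fitting import outcome_arrays  # local import to avoid a cycle

    gain, loss, resp = outcome_arrays(choices, model.domain)
    p = model.accept_probability(gain, loss, params)
    return negative_log_likelihood(resp, p)


# ---------------------------------------------------------------------------
# Model spaces
# ---------------------------------------------------------------------------

def effort_model_space() -> list[ModelSpec]:
    """The eight candidate models fit to the effort tasks.

    Three nested value models (symmetric sensitivity: alpha, lam, mu;
    no sensitivity: lam, mu; no loss aversion: mu) each under linear and
    quadratic encodings, a zero-effort-reference model (gamma, mu), and the
    hybrid loss-aversion + free-encoding model (lam, gamma, mu; alpha = 1).
    """
    return [
        ModelSpec("symmetric_linear", "delta_linear", ("lam", "alpha", "mu"), "effort"),
        ModelSpec("symmetric_quadratic", "delta_quadratic", ("lam", "alpha", "mu"), "effort"),
        ModelSpec("no_sensitivity_linear", "delta_linear", ("lam", "mu"), "effort"),
        ModelSpec("no_sensitivity_quadratic", "delta_quadratic", ("lam", "mu"), "effort"),
        ModelSpec("no_loss_aversion_linear", "delta_linear", ("mu",), "effort"),
        ModelSpec("no_loss_aversion_quadratic", "delta_quadratic", ("mu",), "effort"),
        ModelSpec("zero_effort_reference", "absolute_power", ("gamma", "mu"), "effort"),
        ModelSpec("loss_aversion_encoding", "delta_power", ("lam", "gamma", "mu"), "effort"),
    ]


def financial_model_space() -> list[ModelSpec]:
    """The five candidate models fit to the financial task."""
    return [
        ModelSpec("symmetric_money", "money_linear", ("lam", "alpha", "mu"), "money"),
        ModelSpec("no_sensitivity_money", "money_linear", ("lam", "mu"), "money"),
        ModelSpec("no_loss_aversion_money", "money_linear", ("mu",), "money"),
        ModelSpec("large_money_reference", "money_translated_power", ("gamma", "mu"),
                  "money", bounds=WIDE_MU_BOUNDS),
        ModelSpec("loss_aversion_encoding_money", "money_power_signed",
                  ("lam", "gamma", "mu"), "money", bounds=WIDE_MU_BOUNDS),
    ]


def get_model(name: str) -> ModelSpec:
    """Look up a model by name across both task spaces."""
    for m in effort_model_space() + financial_model_space():
        if m.name == name:
            return m
    raise KeyError(f"no model named {name!r}")
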