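"""Published population anchors for each candidate model's parameters.

Median and interquartile range of the across-subject parameter fits for
every candidate model in each task, as reported for the study cohort.
These anchor the synthetic-cohort generator and the default
confusion-analysis prior: each parameter is drawn log-normal with the given
median and an IQR-matched spread.  Quartiles printed as 0.00 are floored at
a small positive value (a log-normal needs positive quartiles); the floors
(mu 0.005, gamma 0.001) keep such draws behaviourally near-degenerate,
which is what a zero quartile expresses.
"""

from __future__ import annotations

from .cohort import ParamDist

# (median, (q1, q3)) per free parameter, per model, per task
_TABLES: dict[str, dict[str, dict[str, tuple[float, tuple[float, float]]]]] = {
    "EFF": {
        "symmetric_linear": {
            "lam": (1.17, (0.98, 1.31)),
            "alpha": (0.84, (0.67, 1.09)),
            "mu": (1.08, (0.37, 2.25)),
        },
        "symmetric_quadratic": {
            "lam": (0.64, (0.48, 0.80)),
            "alpha": (0.76, (0.52, 1.14)),
            "mu": (0.11, (0.004, 0.63)),
        },
        "no_sensitivity_linear": {
            "lam": (1.20, (0.95, 1.30)),
            "mu": (0.52, (0.33, 0.69)),
        },
        "no_sensitivity_quadratic": {
            "lam": (0.55, (0.43, 0.62)),
            "mu": (0.012, (0.008, 0.014)),
        },
        "no_loss_aversion_linear": {"mu": (0.40, (0.25, 0.62))},
        "no_loss_aversion_quadratic": {"mu": (0.003, (0.002, 0.004))},
        "zero_effort_reference": {
            "gamma": (1.24, (1.00, 1.33)),
            "mu": (0.21, (0.10, 0.67)),
        },
        "loss_aversion_encoding": {
            "lam": (0.71, (0.14, 0.99)),
            "gamma": (1.61, (1.21, 4.21)),
            "mu": (0.064, (0.005, 0.34)),
        },
    },
    "EFF2": {
        "symmetric_linear": {
            "lam": (1.36, (1.14, 2.15)),
            "alpha": (0.97, (0.67, 1.23)),
            "mu": (0.78, (0.24, 2.57)),
        },
        "symmetric_quadratic": {
            "lam": (0.89, (0.61, 0.97)),
            "alpha": (0.65, (0.31, 0.96)),
            "mu": (0.22, (0.016, 2.58)),
        },
        "no_sensitivity_linear": {
            "lam": (1.53, (1.17, 1.77)),
            "mu": (0.49, (0.33, 0.68)),
        },
        "no_sensitivity_quadratic": {
            "lam": (0.73, (0.52, 0.88)),
            "mu": (0.012, (0.008, 0.017)),
        },
        "no_loss_aversion_linear": {"mu": (0.30, (0.27, 0.59))},
        "no_loss_aversion_quadratic": {"mu": (0.005, (0.003, 0.009))},
        "zero_effort_reference": {
            "gamma": (1.50, (1.12, 1.80)),
            "mu": (0.06, (0.03, 0.29)),
        },
        "loss_aversion_encoding": {
            "lam": (0.75, (0.55, 0.90)),
            "gamma": (2.11, (1.20, 2.86)),
            "mu": (0.01, (0.005, 0.65)),
        },
    },
    "FIN": {
        "symmetric_money": {
            "lam": (1.52, (1.13, 2.37)),
            "alpha": (0.74, (0.35, 0.87)),
            "mu": (1.24, (0.49, 10.85)),
        },
        "no_sensitivity_money": {
            "lam": (1.87, (1.22, 3.01)),
            "mu": (0.18, (0.16, 0.39)),
        },
        "no_loss_aversion_money": {"mu": (0.10, (0.05, 0.11))},
        "large_money_reference": {
            "gamma": (0.002, (0.001, 0.71)),
            "mu": (1.54e4, (1.98, 2.55e4)),
        },
        "loss_aversion_encoding_money": {
            "lam": (0.901, (0.74, 1.10)),
            "gamma": (0.001, (0.001, 0.70)),
            "mu": (2.02e4, (2.24, 3.5e4)),
        },
    },
}


def population_medians(task: str, model_name: str) -> dict[str, float]:
    """Point-mass anchor: the published median of each free parameter."""
    table = _TABLES[task][model_name]
    return {p: m for p, (m, _) in table.items()}


def population_distribution(task: str, model_name: str) -> dict[str, ParamDist]:
    """Log-normal, IQR-matched distribution of each free parameter."""
    table = _TABLES[task][model_name]
    return {p: ParamDist("lognormal", m, iqr) for p, (m, iqr) in table.items()}


def empirical_prior(task: str):
    """Confusion-analysis prior anchored at the published population fits."""
    from .bms import ParamPrior

    dists = {name: population_distribution(task, name) for name in _TABLES[task]}
    return ParamPrior(model_dists=dists)
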