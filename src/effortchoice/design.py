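"""Lottery grids for the effort and financial choice tasks.

The effort task presents 50:50 mixed gambles over changes in the viscous
resistance of an arm-reaching movement.  A reference resistance of
b = 35 N·s/m is framed as "0% more/less effort"; gains are percentage
reductions in effort (down to b = 0 at −100%) and losses are percentage
increases (up to b = 70 at +100%), in 10% steps.  The financial task uses
the same 11 × 11 grid over dollar gains ($0–$100) and losses (−$100–$0).

Each unique (gain, loss) pair is shown ``n_repetitions`` times and the
trial order is shuffled per subject with an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Reference damping coefficient (N·s/m), displayed as 0% gain/loss.
B_REFERENCE = 35.0

#: Signed displayed percentages: negative = gain (less effort), positive = loss.
PERCENT_GRID = tuple(range(-100, 101, 10))

#: Dollar levels used on each arm of the financial grid.
USD_GRID = tuple(range(0, 101, 10))

TASKS = ("EFF", "EFF2", "FIN")


def percent_to_b(percent_shown: float) -> float:
    """Map a displayed signed percent change in effort to a damping coefficient.

    b = 35 · (1 + percent/100), so −100% → 0 N·s/m, 0% → 35, +100% → 70.
    Off-grid values are rejected: the display grid is multiples of 10 in
    [−100, 100].
    """
    if percent_shown not in PERCENT_GRID:
        raise ValueError(
            f"percent_shown={percent_shown!r} is off-grid; valid values are "
            "multiples of 10 in [-100, 100]"
        )
    return B_REFERENCE * (1.0 + percent_shown / 100.0)


def b_to_percent(b: float) -> int:
    """Inverse of :func:`percent_to_b`, exact on grid values."""
    percent = 100.0 * (b / B_REFERENCE - 1.0)
    rounded = int(round(percent))
    if rounded not in PERCENT_GRID or not np.isclose(percent, rounded, atol=1e-9):
        raise ValueError(
            f"b={b!r} N·s/m is not on the lottery grid "
            f"(multiples of 3.5 in [0, 70])"
        )
    return rounded


@dataclass(frozen=True)
class EffortLevel:
    """One arm of an effort lottery: displayed percent and its resistance."""

    percent_shown: int

    @property
    def b(self) -> float:
        return percent_to_b(self.percent_shown)


@dataclass(frozen=True)
class Lottery:
    """A 50:50 mixed gamble: a gain arm and a loss arm.

    For effort tasks the arms are signed percents (gain ≤ 0, loss ≥ 0);
    for the financial task they are dollars (gain ≥ 0, loss ≤ 0).
    """

    gain: float
    loss: float
    task: str
    p_gain: float = 0.5

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.p_gain != 0.5:
            raise ValueError("lotteries are 50:50 mixed gambles; p_gain must be 0.5")
        if self.task == "FIN":
            if self.gain < 0 or self.loss > 0:
                raise ValueError("FIN gain arm must be ≥ $0 and loss arm ≤ $0")
        else:
            if self.gain > 0 or self.loss < 0:
                raise ValueError(
                    "effort gain arm must have percent ≤ 0 (less effort) "
                    "and loss arm percent ≥ 0"
                )


def _shuffled_grid(rows: list[dict], n_repetitions: int, rng_seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(rng_seed)
    trials = rows * n_repetitions
    order = rng.permutation(len(trials))
    out = pd.DataFrame([trials[i] for i in order])
    # repetition = how many times this unique pair has now been seen
    out["repetition"] = out.groupby(["gain", "loss"]).cumcount() + 1
    out["trial_index"] = np.arange(len(out))
    return out


def build_effort_grid(
    n_repetitions: int = 3, rng_seed: int = 0, task: str = "EFF"
) -> pd.DataFrame:
    """Full 11 × 11 effort lottery grid, each pair repeated ``n_repetitions`` times.

    Returns the tidy trial table with columns
    ``trial_index, task, gain_pct, loss_pct, b_gain, b_loss, repetition``;
    gains are stored as signed percents ≤ 0.  The default 3 repetitions give
    the 363-trial session.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be ≥ 1")
    if task not in ("EFF", "EFF2"):
        raise ValueError("effort grids have task 'EFF' or 'EFF2'")
    rows = [
        {"gain": -g, "loss": l}
        for g in range(0, 101, 10)
        for l in range(0, 101, 10)
    ]
    df = _shuffled_grid(rows, n_repetitions, rng_seed)
    df["task"] = task
    df = df.rename(columns={"gain": "gain_pct", "loss": "loss_pct"})
    df["b_gain"] = B_REFERENCE * (1.0 + df["gain_pct"] / 100.0)
    df["b_loss"] = B_REFERENCE * (1.0 + df["loss_pct"] / 100.0)
    return df[
        ["trial_index", "task", "gain_pct", "loss_pct", "b_gain", "b_loss", "repetition"]
    ]


def build_financial_grid(n_repetitions: int = 3, rng_seed: int = 0) -> pd.DataFrame:
    """Financial analogue of the effort grid: $0–$100 gains vs −$100–$0 losses.

    Columns: ``trial_index, task, usd_gain, usd_loss, repetition``.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be ≥ 1")
    rows = [
        {"gain": g, "loss": -l}
        for g in range(0, 101, 10)
        for l in range(0, 101, 10)
    ]
    df = _shuffled_grid(rows, n_repetitions, rng_seed)
    df["task"] = "FIN"
    df = df.rename(columns={"gain": "usd_gain", "loss": "usd_loss"})
    return df[["trial_index", "task", "usd_gain", "usd_loss", "repetition"]]


def outcome_columns(task: str) -> tuple[str, str]:
    """Names of the (gain, loss) outcome columns for a task's trial tables."""
    if task == "FIN":
        return "usd_gain", "usd_loss"
    return "gain_pct", "loss_pct"
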