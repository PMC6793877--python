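"""CSV/JSON interchange: validated choice tables, fit tables, BMS reports.

The trial-table dialect is one row per trial with columns
``subject_id, task, trial_index, gain_pct, loss_pct`` (effort tasks, signed
percents on the 10%-grid) or ``usd_gain, usd_loss`` (financial task),
``response`` (1 = accept, 0 = reject) and optional ``strength`` and
``rt_ms``.  Validation is collective: every malformed row is reported in
one error, with row numbers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bms import BMSResult

_EFFORT_GRID = set(range(-100, 101, 10))


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialised into the manifest."""

    task: str = "EFF"
    models: str = "all"
    n_restarts: int = 20
    n_subjects: int = 20
    n_mc: int = 8
    seed: int = 0
    out_dir: str = "out"
    extra: dict = field(default_factory=dict)


def read_choices(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level choice CSV.

    Rejects off-grid gain/loss levels (naming the 10%-step rule), unknown
    tasks and non-binary responses, reporting all bad rows together.
    """
    df = pd.read_csv(path)
    errors: list[str] = []
    required = {"subject_id", "task", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    tasks = set(df["task"].unique())
    if not tasks <= {"EFF", "EFF2", "FIN"}:
        raise ValueError(f"{path}: unknown task values {sorted(tasks - {'EFF', 'EFF2', 'FIN'})}")

    is_fin = df["task"] == "FIN"
    if is_fin.any():
        for col in ("usd_gain", "usd_loss"):
            if col not in df.columns:
                raise ValueError(f"{path}: FIN rows require column {col!r}")
    if (~is_fin).any():
        for col in ("gain_pct", "loss_pct"):
            if col not in df.columns:
                raise ValueError(f"{path}: effort rows require column {col!r}")

    for i, row in df.iterrows():
        if row["task"] == "FIN":
            g, l = row["usd_gain"], row["usd_loss"]
            if g not in _EFFORT_GRID or not 0 <= g <= 100:
                errors.append(f"row {i}: usd_gain={g} off the $10-step grid [0, 100]")
            if -l not in _EFFORT_GRID or not -100 <= l <= 0:
                errors.append(f"row {i}: usd_loss={l} off the $10-step grid [-100, 0]")
        else:
            g, l = row["gain_pct"], row["loss_pct"]
            if g not in _EFFORT_GRID or g > 0:
                errors.append(
                    f"row {i}: gain_pct={g} invalid; gains are multiples of 10 in [-100, 0]")
            if l not in _EFFORT_GRID or l < 0:
                errors.append(
                    f"row {i}: loss_pct={l} invalid; losses are multiples of 10 in [0, 100]")
        if row["response"] not in (0, 1):
            errors.append(f"row {i}: response={row['response']!r} must be 0 or 1")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows:\n" + "\n".join(errors))
    df["response"] = df["response"].astype(int)
    return df


def write_choices(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_fits(fits: pd.DataFrame, path: str | Path) -> None:
    """Tidy fit table (one row per subject × model) to CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fits.to_csv(path, index=False)


def bms_report(bms: BMSResult, winner: dict) -> dict:
    return {
        "models": bms.model_names,
        "dirichlet_alpha": bms.dirichlet_alpha.tolist(),
        "expected_freq": bms.expected_freq.tolist(),
        "xp": bms.xp.tolist(),
        "pxp": bms.pxp.tolist(),
        "bor": bms.bor,
        "n_subjects": bms.n_subjects,
        "winner": winner,
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def write_manifest(config: RunConfig, path: str | Path, **extra) -> None:
    """Record the run configuration and seeds so a run can be reproduced."""
    payload = {"config": asdict(config), **extra}
    write_json(payload, path)
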