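"""Descriptive and inferential statistics over lottery choices and fits.

Rejection matrices and their marginals summarise raw choice behaviour on
the 11 × 11 gain × loss grid; a tie-corrected Mann-Kendall test checks that
rejection rises monotonically with the loss level and falls with the gain
level.  Subjective-value tables and the loss/gain valuation ratio translate
fitted parameters back into per-condition valuations.  Parameter
comparisons (against unity, between tasks, and test-retest correlation)
delegate to standard routines; only the Mann-Kendall statistic is computed
from its definition because trend-test conventions vary between packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import outcome_columns
from .models import ModelSpec


# ---------------------------------------------------------------------------
# Rejection matrices
# ---------------------------------------------------------------------------

@dataclass
class RejectionMatrix:
    """Per-cell rejection frequencies on the gain × loss grid.

    ``matrix`` is indexed by gain level (rows) × loss level (columns), each
    cell the mean rejection rate over repetitions and subjects;
    ``dispersion`` is the across-subject SD of per-subject cell rates;
    ``gain_marginal``/``loss_marginal`` are mean rejection versus one arm,
    averaged over the other.
    """

    matrix: pd.DataFrame
    dispersion: pd.DataFrame
    gain_marginal: pd.Series
    loss_marginal: pd.Series
    n_subjects: int


def rejection_matrix(choices: pd.DataFrame) -> RejectionMatrix:
    """Tabulate rejection frequency per (gain, loss) cell.

    Cells never presented are NaN, not imputed.  Works for effort
    (percent columns) and financial (dollar columns) trial tables.
    """
    task = choices["task"].iloc[0]
    gcol, lcol = outcome_columns(task)
    df = choices.copy()
    df["rejected"] = 1 - df["response"]
    per_subject = (
        df.groupby(["subject_id", gcol, lcol])["rejected"].mean().reset_index()
    )
    mat = (
        per_subject.groupby([gcol, lcol])["rejected"].mean().unstack(lcol)
    )
    disp = (
        per_subject.groupby([gcol, lcol])["rejected"].std(ddof=0).unstack(lcol)
    )
    return RejectionMatrix(
        matrix=mat,
        dispersion=disp,
        gain_marginal=mat.mean(axis=1),
        loss_marginal=mat.mean(axis=0),
        n_subjects=df["subject_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# Mann-Kendall trend test
# ---------------------------------------------------------------------------

@dataclass
class TrendTest:
    s: int
    z: float
    p_value: float
    n: int


def mann_kendall_trend(sequence) -> TrendTest:
    """Tie-corrected Mann-Kendall monotonic-trend test.

    S = Σ_{i<j} sign(x_j − x_i); under H0 the normal approximation has
    variance [n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)] / 18 over tie groups of
    size t, with a ±1 continuity correction on S.  Two-sided p-value.
    """
    x = np.asarray(sequence, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Mann-Kendall requires at least 4 observations")
    s = int(np.sum(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)]))
    _, tie_counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5) - np.sum(
        tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var <= 0 or s == 0:
        return TrendTest(s=s, z=0.0, p_value=1.0, n=n)
    z = (s - np.sign(s)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TrendTest(s=s, z=float(z), p_value=float(min(p, 1.0)), n=n)


# ---------------------------------------------------------------------------
# Subjective-value tables and the loss/gain ratio
# ---------------------------------------------------------------------------

def _condition_levels(model: ModelSpec) -> np.ndarray:
    # the ten nonzero |change| levels of the grid, in raw units
    if model.domain == "money":
        return np.arange(10.0, 101.0, 10.0)
    return np.arange(3.5, 35.01, 3.5)


def sv_by_condition(params, model: ModelSpec) -> pd.DataFrame:
    """Subjective value of each nonzero gain and loss condition.

    Values are measured relative to the sure (reference) outcome, so that
    gains are positive and losses negative for every encoding.
    """
    levels = _condition_levels(model)
    sure = model.sure_bet_utility(params)
    if model.domain == "money":
        gain_raw, loss_raw = levels, -levels
    else:
        gain_raw, loss_raw = 35.0 - levels, 35.0 + levels
    return pd.DataFrame({
        "condition": levels,
        "sv_gain": np.asarray(model.arm_value(gain_raw, params)) - sure,
        "sv_loss": np.asarray(model.arm_value(loss_raw, params)) - sure,
    })


def loss_gain_ratio(params, model: ModelSpec) -> float:
    """Mean over conditions of |SV(loss)| / |SV(gain)| at matched |change|.

    Equals 1 exactly for symmetric valuation (lam = 1, gamma = 1, alpha
    free).  Conditions with zero gain value are excluded (only nonzero
    conditions have defined ratios).
    """
    tab = sv_by_condition(params, model)
    ok = tab["sv_gain"].abs() > 0
    if not ok.any():
        raise ValueError("all gain conditions have zero subjective value")
    return float((tab.loc[ok, "sv_loss"].abs() / tab.loc[ok, "sv_gain"].abs()).mean())


# ---------------------------------------------------------------------------
# Parameter comparisons
# ---------------------------------------------------------------------------

def compare_parameters(values_a, values_b=None, null_value: float = 1.0) -> dict:
    """Compare fitted parameters against a null value or between tasks.

    One-sample mode (``values_b`` is None): Shapiro-Wilk normality check and
    Wilcoxon signed-rank of ``values_a`` against ``null_value``.  Paired
    mode: the same on paired differences, plus Pearson correlation and the
    count of subjects whose two estimates fall on the same side of
    ``null_value`` (directionality consistency).
    """
    a = np.asarray(values_a, dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    report: dict = {"n": len(a), "null_value": null_value}
    if values_b is None:
        diffs = a - null_value
        report["median"] = float(np.median(a))
        report["shapiro_p"] = float(sps.shapiro(a).pvalue)
        if np.allclose(diffs, 0.0):
            report["wilcoxon_p"] = 1.0
        else:
            report["wilcoxon_p"] = float(sps.wilcoxon(diffs).pvalue)
        return report
    b = np.asarray(values_b, dtype=float)
    if len(b) != len(a):
        raise ValueError("paired comparison requires equal-length vectors")
    diffs = a - b
    report["median_a"] = float(np.median(a))
    report["median_b"] = float(np.median(b))
    report["shapiro_p"] = float(sps.shapiro(diffs).pvalue) if not np.allclose(
        diffs, diffs[0]) else 1.0
    report["wilcoxon_p"] = 1.0 if np.allclose(diffs, 0.0) else float(
        sps.wilcoxon(a, b).pvalue)
    if np.std(a) > 0 and np.std(b) > 0:
        r, rp = sps.pearsonr(a, b)
        report["pearson_r"], report["pearson_p"] = float(r), float(rp)
    else:
        report["pearson_r"] = report["pearson_p"] = float("nan")
    same_side = ((a > null_value) & (b > null_value)) | ((a < null_value) & (b < null_value))
    report["consistent_directionality"] = int(same_side.sum())
    return report


def sv_condition_anova(fits: pd.DataFrame, model: ModelSpec) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA of SV on domain × condition.

    Builds the long per-subject table of |subjective value| for each gain
    and loss condition from a tidy fit table (one row per subject with this
    model's parameter columns) and delegates to ``pingouin.rm_anova``.
    """
    import pingouin as pg

    rows = []
    for _, fit_row in fits.iterrows():
        params = {p: fit_row[p] for p in model.free_params}
        tab = sv_by_condition(params, model)
        for _, r in tab.iterrows():
            rows.append({"subject_id": fit_row["subject_id"], "domain": "gain",
                         "condition": r["condition"], "sv": abs(r["sv_gain"])})
            rows.append({"subject_id": fit_row["subject_id"], "domain": "loss",
                         "condition": r["condition"], "sv": abs(r["sv_loss"])})
    long = pd.DataFrame(rows)
    return pg.rm_anova(data=long, dv="sv", within=["domain", "condition"],
                       subject="subject_id", detailed=True)
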