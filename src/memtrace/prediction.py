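"""Longitudinal prediction shift: expected scores 8 months after first scan.

At the follow-up scan every memory is 8 months older, i.e. two positions
further along the sampled age grid (0.5, 4, 8, 12, 16, 20, 24, 60 months).
The predicted follow-up score profile therefore shifts the first-scan
profile forwards by two time points, with two boundary assumptions: ages
beyond the 24-month sample (28 and 32 months) are assumed to sit at the
24-month level, and 60-month-old memories are assumed unchanged at 68
months.  Each original age gets a directional hypothesis — increase,
decrease, or no change — from the sign of (predicted - original), and the
follow-up data are tested with paired t tests, one-tailed where a change
was hypothesised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from memtrace.design import DEFAULT_TIME_POINTS

FOLLOWUP_MONTHS = 8.0


@dataclass(frozen=True)
class PredictionSet:
    """Per original age: the follow-up age, its source age, and a direction."""

    table: pd.DataFrame  # original_months, new_months, source_months, direction

    def __post_init__(self) -> None:
        dirs = set(self.table["direction"])
        if not dirs <= {"increase", "decrease", "no_change"}:
            raise ValueError(f"invalid directions: {dirs}")


def _shift_mapping(time_points: tuple[float, ...]) -> pd.DataFrame:
    """original age -> follow-up age -> source age on the first-scan grid.

    The grid samples consecutive 4-month steps up to its penultimate age
    plus one remote age, so "8 months later" means two positions along the
    grid.  Ages that shift past the penultimate sampled age saturate at its
    level (no first-scan data exists beyond it), and the final remote age
    is assumed unchanged.
    """
    tps = sorted(time_points)
    T = len(tps)
    if T < 3:
        raise ValueError("need at least 3 sampled ages to shift by two positions")
    rows = []
    for i, tp in enumerate(tps):
        if i == T - 1:
            source = tps[-1]  # remote boundary: assumed unchanged
            new = tp + FOLLOWUP_MONTHS
        elif i + 2 <= T - 2:
            source = tps[i + 2]
            new = tps[i + 2]  # lands exactly on a sampled age
        else:
            source = tps[T - 2]  # saturate at the penultimate sampled age
            new = tp + FOLLOWUP_MONTHS
        rows.append(
            {"original_months": tp, "new_months": new, "source_months": source}
        )
    return pd.DataFrame(rows)


def shift_profile(
    exp1_scores: pd.Series | dict[float, float],
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS,
) -> pd.Series:
    """Predicted follow-up group means, indexed by the new (shifted) ages.

    ``exp1_scores`` maps each first-scan age to its group mean score; every
    age of the sampled grid must be present.
    """
    s = pd.Series(exp1_scores, dtype=float)
    missing = set(time_points) - set(s.index)
    if missing:
        raise ValueError(f"missing time points: {sorted(missing)}")
    mapping = _shift_mapping(tuple(sorted(time_points)))
    pred = s.loc[mapping["source_months"]].to_numpy()
    return pd.Series(pred, index=mapping["new_months"].to_numpy(), name="predicted")


def directional_hypotheses(
    exp1_scores: pd.Series | dict[float, float],
    tol: float = 0.0,
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS,
) -> PredictionSet:
    """Directional hypotheses from the shifted profile.

    The direction for each original age is the sign of (predicted -
    original); differences within ``tol`` count as no change (the default
    treats only exact ties — the saturated boundary ages — as no change).
    """
    s = pd.Series(exp1_scores, dtype=float)
    missing = set(time_points) - set(s.index)
    if missing:
        raise ValueError(f"missing time points: {sorted(missing)}")
    mapping = _shift_mapping(tuple(sorted(time_points)))
    pred = s.loc[mapping["source_months"]].to_numpy()
    orig = s.loc[mapping["original_months"]].to_numpy()
    diff = pred - orig
    direction = np.where(
        np.abs(diff) <= tol + 1e-12,
        "no_change",
        np.where(diff > 0, "increase", "decrease"),
    )
    table = mapping.assign(direction=direction)
    return PredictionSet(table=table)


def evaluate_predictions(
    exp1: pd.DataFrame,
    exp2: pd.DataFrame,
    predictions: PredictionSet,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each directional hypothesis with a paired t on follow-up scores.

    ``exp1`` and ``exp2`` are subject x age score tables for the same
    subjects, both indexed by the *original* ages.  Hypothesised changes
    get one-tailed tests in the predicted direction; no-change hypotheses
    get two-tailed tests and count as supported when the test fails to
    reject at ``alpha``.

    Returns one row per original age: direction, t, df, p, supported.
    """
    if exp1.shape != exp2.shape or not exp1.index.equals(exp2.index):
        raise ValueError("experiment tables must share subjects and shape")
    rows = []
    for rec in predictions.table.itertuples():
        tp = rec.original_months
        x1 = exp1[tp].to_numpy(float)
        x2 = exp2[tp].to_numpy(float)
        alt = {
            "increase": "greater",
            "decrease": "less",
            "no_change": "two-sided",
        }[rec.direction]
        if np.std(x2 - x1, ddof=1) == 0:
            t, p = 0.0, 1.0 if alt == "two-sided" else 0.5
        else:
            t, p = sps.ttest_rel(x2, x1, alternative=alt)
        if rec.direction == "no_change":
            supported = p >= alpha
        else:
            supported = p < alpha
        rows.append(
            {
                "original_months": tp,
                "new_months": rec.new_months,
                "direction": rec.direction,
                "t": float(t),
                "df": len(x1) - 1,
                "p": float(p),
                "supported": bool(supported),
            }
        )
    return pd.DataFrame(rows)


def prediction_summary(report: pd.DataFrame) -> dict[str, int]:
    """Counts of supported hypotheses, for a JSON-style summary."""
    return {
        "n_supported": int(report["supported"].sum()),
        "n_hypotheses": int(len(report)),
    }
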