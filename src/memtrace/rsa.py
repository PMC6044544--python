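"""Neural representation scores from cross-session pattern similarity.

The core statistic: for each memory, the mean Pearson correlation between
its recall-trial patterns across different sessions (within-memory
similarity) minus the mean correlation between its trials and those of the
other memories of the same set (between-memory similarity).  A score above
zero indicates a reproducible, memory-specific activity pattern.  The
16-memory design splits into two sets of 8 ages that are scored separately;
the per-memory scores are then averaged across the two memories at each
age.  A matched-age variant replaces the all-other baseline with the single
identically aged memory of the other set.

Raw correlations are averaged without Fisher transformation by default
(``fisher=True`` switches to averaging z-transformed values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from memtrace.glm import PatternMatrix

VARIANTS = ("all-other", "matched-age")


class FilterResult(NamedTuple):
    """Vividness-filtered trials plus the memories left unscorable."""

    trials: pd.DataFrame
    unscorable: tuple[int, ...]


@dataclass
class MemoryRSM:
    """Memory-by-memory matrix of mean cross-session Pearson correlations.

    The diagonal holds within-memory similarities (not forced to 1);
    entries for unscorable memories are NaN.  ``labels`` carries one row
    per matrix row: memory_id, time_point_months, set.
    """

    matrix: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square and match the labels")
        finite = np.isfinite(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("similarity matrix must be symmetric")
        self.matrix = m

    def index_of(self, memory_id: int) -> int:
        pos = np.flatnonzero(self.labels["memory_id"].to_numpy() == memory_id)
        if len(pos) != 1:
            raise KeyError(f"memory {memory_id} not in RSM labels")
        return int(pos[0])


def _as_array(p: PatternMatrix | np.ndarray) -> np.ndarray:
    return p.data if isinstance(p, PatternMatrix) else np.asarray(p, dtype=float)


def filter_vivid_trials(trials: pd.DataFrame, threshold: int = 3) -> FilterResult:
    """Drop trials rated below ``threshold`` vividness; flag fragile memories.

    A memory stays scorable only if it retains at least 2 trials spread over
    at least 2 distinct sessions; otherwise it is flagged as unscorable
    (never silently dropped).  ``threshold=1`` keeps everything.
    """
    viv = trials["vividness"].to_numpy()
    if np.any((viv < 1) | (viv > 5)):
        raise ValueError("vividness ratings must lie in 1..5")
    kept = trials[trials["vividness"] >= threshold].copy()
    unscorable = []
    for mid in sorted(trials["memory_id"].unique()):
        sub = kept[kept["memory_id"] == mid]
        if len(sub) < 2 or sub["session"].nunique() < 2:
            unscorable.append(int(mid))
    return FilterResult(trials=kept, unscorable=tuple(unscorable))


def _check_trial_variance(pat: np.ndarray, trial_ids: np.ndarray) -> None:
    flat = pat.std(axis=1) == 0
    if flat.any():
        raise ValueError(
            f"zero-variance trial patterns for trials {trial_ids[flat].tolist()}"
        )


def _pair_mean(
    corr: np.ndarray, sess: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, same: bool
) -> float:
    block = corr[np.ix_(idx_a, idx_b)]
    cross = sess[idx_a][:, None] != sess[idx_b][None, :]
    if same:
        cross &= np.triu(np.ones_like(cross, dtype=bool), k=1)
    if not cross.any():
        return np.nan
    return float(block[cross].mean())


def memory_rsm(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    fisher: bool = False,
) -> MemoryRSM:
    """Mean cross-session trial-pair Pearson correlation for every memory pair.

    Similarity is averaged over all trial pairs drawn from different
    sessions (for the diagonal: unordered distinct trial pairs, which the
    design makes cross-session automatically).  Pattern rows must align
    with ``trials`` rows.
    """
    pat = _as_array(p)
    if pat.shape[0] != len(trials):
        raise ValueError("pattern rows must match trial rows")
    _check_trial_variance(pat, trials["trial"].to_numpy())
    corr = np.corrcoef(pat)
    if fisher:
        corr = np.arctanh(np.clip(corr, -1 + 1e-12, 1 - 1e-12))
    sess = trials["session"].to_numpy()
    labels = (
        trials[["memory_id", "time_point_months", "set"]]
        .drop_duplicates()
        .sort_values("memory_id")
        .reset_index(drop=True)
    )
    ids = labels["memory_id"].to_numpy()
    index = {mid: np.flatnonzero(trials["memory_id"].to_numpy() == mid) for mid in ids}
    m = len(ids)
    out = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            val = _pair_mean(corr, sess, index[ids[i]], index[ids[j]], same=i == j)
            out[i, j] = out[j, i] = val
    if fisher:
        out = np.tanh(out)
    return MemoryRSM(matrix=out, labels=labels)


def cross_session_similarity(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    mem_a: int,
    mem_b: int,
) -> float:
    """Mean Pearson r over cross-session trial pairs of two memories.

    With ``mem_a == mem_b`` this is the within-memory similarity over
    unordered distinct trial pairs.
    """
    pat = _as_array(p)
    sess = trials["session"].to_numpy()
    mids = trials["memory_id"].to_numpy()
    idx_a = np.flatnonzero(mids == mem_a)
    idx_b = np.flatnonzero(mids == mem_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"no trials for memories {mem_a}, {mem_b}")
    sub = np.concatenate([idx_a, idx_b])
    _check_trial_variance(pat[sub], trials["trial"].to_numpy()[sub])
    corr = np.corrcoef(pat)
    val = _pair_mean(corr, sess, idx_a, idx_b, same=mem_a == mem_b)
    if np.isnan(val):
        raise ValueError(
            f"no eligible cross-session trial pairs between memories "
            f"{mem_a} and {mem_b}"
        )
    return val


def _score_from_rsm(rsm: MemoryRSM, memory_id: int, variant: str) -> float:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    i = rsm.index_of(memory_id)
    within = rsm.matrix[i, i]
    row = rsm.labels.iloc[i]
    if variant == "all-other":
        same_set = (rsm.labels["set"] == row["set"]).to_numpy()
        others = same_set.copy()
        others[i] = False
        between = np.nanmean(rsm.matrix[i, others])
    else:
        mate = (
            (rsm.labels["time_point_months"] == row["time_point_months"])
            & (rsm.labels["set"] != row["set"])
        ).to_numpy()
        if mate.sum() != 1:
            raise ValueError(
                f"memory {memory_id} has no unique identically aged "
                "counterpart in the other set"
            )
        between = rsm.matrix[i, np.flatnonzero(mate)[0]]
    return float(within - between)


def neural_representation_score(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    memory_id: int,
    variant: str = "all-other",
) -> float:
    """Within-memory similarity minus the between-memory baseline.

    ``all-other``: baseline is the mean similarity to the other memories of
    the same set.  ``matched-age``: baseline is the similarity to the single
    identically aged memory of the other set.
    """
    return _score_from_rsm(memory_rsm(p, trials), memory_id, variant)


def timepoint_scores(
    p: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    variant: str = "all-other",
    unscorable: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Per-time-point neural representation scores for one subject.

    Per-memory scores are averaged across the (up to two) memories at each
    age; per-set sub-scores are retained for replication checks.  Returns a
    frame indexed by age with columns ``score``, one ``score_<set>`` per
    set, ``n_memories`` (scorable count) and ``incomplete`` (True when a
    memory at that age was unscorable).
    """
    rsm = memory_rsm(p, trials)
    labels = rsm.labels
    sets = sorted(labels["set"].unique())
    rows = []
    for tp in sorted(labels["time_point_months"].unique()):
        here = labels[labels["time_point_months"] == tp]
        per_set: dict[str, float] = {s: np.nan for s in sets}
        vals = []
        for rec in here.itertuples():
            if rec.memory_id in unscorable:
                continue
            s = _score_from_rsm(rsm, rec.memory_id, variant)
            if np.isnan(s):
                continue
            per_set[rec.set] = s
            vals.append(s)
        rows.append(
            {
                "time_point_months": tp,
                "score": float(np.mean(vals)) if vals else np.nan,
                **{f"score_{s}": per_set[s] for s in sets},
                "n_memories": len(vals),
                "incomplete": len(vals) < len(here),
            }
        )
    return pd.DataFrame(rows).set_index("time_point_months")


def group_rsm(rsms: list[MemoryRSM], display: bool = False) -> MemoryRSM:
    """Element-wise mean RSM across subjects.

    With ``display=True`` the averaged values are replaced by their ranks
    (ties averaged) linearly rescaled to [0, 1], the usual presentation for
    group similarity matrices.
    """
    ref = rsms[0].labels
    for r in rsms[1:]:
        if not r.labels.equals(ref):
            raise ValueError("subject RSMs must share identical memory labels")
    mean = np.mean([r.matrix for r in rsms], axis=0)
    if display:
        flat = rankdata(mean, axis=None)
        if flat.max() > flat.min():
            flat = (flat - flat.min()) / (flat.max() - flat.min())
        else:
            flat = np.full_like(flat, 0.5)
        mean = flat.reshape(mean.shape)
    return MemoryRSM(matrix=mean, labels=ref.copy())


def between_memory_profile(rsms: list[MemoryRSM]) -> pd.DataFrame:
    """Per-subject, per-age mean between-memory similarity (the score baseline).

    For each memory the baseline is the mean similarity to the other
    memories of its set; values are averaged over the memories at each age.
    Rows are subjects, columns are ages — ready for a stability ANOVA.
    """
    ref = rsms[0].labels
    tps = sorted(ref["time_point_months"].unique())
    out = np.empty((len(rsms), len(tps)))
    for s, rsm in enumerate(rsms):
        if not rsm.labels.equals(ref):
            raise ValueError("subject RSMs must share identical memory labels")
        for t, tp in enumerate(tps):
            vals = []
            for rec in rsm.labels[rsm.labels["time_point_months"] == tp].itertuples():
                i = rsm.index_of(rec.memory_id)
                others = (rsm.labels["set"] == rec.set).to_numpy()
                others[i] = False
                vals.append(np.nanmean(rsm.matrix[i, others]))
            out[s, t] = np.mean(vals)
    return pd.DataFrame(out, columns=tps)


def stack_scores(per_subject: list[pd.DataFrame], column: str = "score") -> pd.DataFrame:
    """Stack per-subject time-point score frames into a subject x age table."""
    rows = [df[column] for df in per_subject]
    table = pd.DataFrame(rows).reset_index(drop=True)
    table.index.name = "subject"
    return table
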