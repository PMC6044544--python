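"""Experiment design: recall schedules for the 12-session / 96-trial paradigm.

The scanning design recalls each of 16 autobiographical memories (2 per
memory age, one in each of two interleaved sets) six times across 12 short
sessions of 8 trials, under two constraints: no memory repeats within a
session, and the two memories sharing an age are never recalled in the same
session.  Dedicating alternate sessions to one set satisfies both
constraints deterministically; trial order within a session is randomised.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Memory ages in months at the first scan.
DEFAULT_TIME_POINTS = (0.5, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 60.0)

SCHEDULE_COLUMNS = ["trial", "session", "memory_id", "time_point_months", "set", "order"]


@dataclass(frozen=True)
class DesignSpec:
    """Counts defining a recall-scanning design.

    The identity ``repetitions * memories_per_timepoint * n_timepoints ==
    n_sessions * trials_per_session`` must hold for the trial budget to be
    consistent.
    """

    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    memories_per_timepoint: int = 2
    repetitions: int = 6
    n_sessions: int = 12
    trials_per_session: int = 8

    def __post_init__(self) -> None:
        if self.memories_per_timepoint < 1:
            raise ValueError("memories_per_timepoint must be >= 1")
        if len(self.time_points) != len(set(self.time_points)):
            raise ValueError("time_points must be distinct")
        n_mem = self.memories_per_timepoint * len(self.time_points)
        if self.repetitions * n_mem != self.n_sessions * self.trials_per_session:
            raise ValueError(
                "infeasible design: repetitions * memories_per_timepoint * "
                f"n_timepoints = {self.repetitions * n_mem} but n_sessions * "
                f"trials_per_session = {self.n_sessions * self.trials_per_session}"
            )

    @property
    def n_memories(self) -> int:
        return self.memories_per_timepoint * len(self.time_points)

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def set_labels(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.memories_per_timepoint])


def memory_table(spec: DesignSpec) -> pd.DataFrame:
    """One row per memory: id, age in months, and set label.

    Memory ids are integers ``0 .. n_memories - 1``, ordered set-major so
    that set A holds one memory per time point, then set B, and so on.
    """
    rows = []
    mid = 0
    for set_label in spec.set_labels:
        for tp in spec.time_points:
            rows.append({"memory_id": mid, "time_point_months": tp, "set": set_label})
            mid += 1
    return pd.DataFrame(rows)


def build_schedule(spec: DesignSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Build a full trial schedule satisfying the co-occurrence constraints.

    Sessions cycle through the memory sets (A, B, A, B, ... for two sets);
    each session presents every memory of its set exactly once, in a seeded
    random order.  Because same-age memories live in different sets, they can
    never co-occur, and no memory repeats within a session.

    Parameters
    ----------
    spec:
        Design counts; its consistency identity must hold (enforced at
        construction).
    seed:
        Integer seed or a ``numpy.random.Generator``.  Fixed seeds give
        bit-identical schedules.

    Returns
    -------
    pandas.DataFrame
        Columns ``trial`` (0-based across the experiment), ``session``
        (1-based), ``memory_id``, ``time_point_months``, ``set``, ``order``
        (0-based within session).
    """
    if spec.trials_per_session != len(spec.time_points):
        raise ValueError(
            "infeasible design for set-per-session layout: trials_per_session "
            f"({spec.trials_per_session}) must equal the number of time points "
            f"({len(spec.time_points)})"
        )
    rng = np.random.default_rng(seed)
    mem = memory_table(spec)
    rows = []
    trial = 0
    for session in range(1, spec.n_sessions + 1):
        set_label = spec.set_labels[(session - 1) % len(spec.set_labels)]
        block = mem[mem["set"] == set_label]
        order = rng.permutation(len(block))
        block = block.iloc[order].reset_index(drop=True)
        for pos in range(len(block)):
            rows.append(
                {
                    "trial": trial,
                    "session": session,
                    "memory_id": int(block.loc[pos, "memory_id"]),
                    "time_point_months": float(block.loc[pos, "time_point_months"]),
                    "set": block.loc[pos, "set"],
                    "order": pos,
                }
            )
            trial += 1
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def validate_schedule(schedule: pd.DataFrame, spec: DesignSpec) -> None:
    """Raise ``ValueError`` if the schedule violates any design invariant."""
    if len(schedule) != spec.n_trials:
        raise ValueError(f"expected {spec.n_trials} trials, got {len(schedule)}")
    counts = schedule.groupby("memory_id").size()
    if not (counts == spec.repetitions).all():
        raise ValueError("each memory must occur exactly `repetitions` times")
    per_sess = schedule.groupby("session")
    for session, block in per_sess:
        if len(block) != spec.trials_per_session:
            raise ValueError(f"session {session} has {len(block)} trials")
        if block["memory_id"].duplicated().any():
            raise ValueError(f"memory repeated within session {session}")
        if block["time_point_months"].duplicated().any():
            raise ValueError(
                f"same-age memories co-occur in session {session}"
            )
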