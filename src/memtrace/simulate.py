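"""Synthetic cohorts with a known ground-truth consolidation profile.

Each simulated subject recalls 16 memories (2 sets x 8 ages) six times
across 12 sessions.  A trial's voxel pattern is

    amplitude(age) * memory_signature
    + shared_weight * common_retrieval_vector
    + spatially correlated noise,

where each memory's signature is a fixed unit-norm vector drawn once, the
common vector models retrieval-related activity shared by all trials, and
the noise is Gaussian-smoothed white noise so the noise covariance is
non-diagonal (giving the whitening stage something to exploit).  Session
residuals are drawn from the same noise process.  Per-trial vividness
ratings are drawn with high mass on 4-5, matching the roughly 5.2-5.6 of 6
trials per memory that survive a low-vividness exclusion.

The amplitude profile is the simulation's ground truth: downstream recovery
tests compare estimated group score profiles against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from memtrace.design import DesignSpec, build_schedule, memory_table

#: Nonmonotonic default amplitude profile across the 8 default ages:
#: undetectable at 0.5 months, rising over the first year, dipping at
#: 16-20 months, strong again at 24-60 months.
DEFAULT_AMPLITUDES = (0.0, 0.6, 0.7, 0.9, 0.3, 0.1, 1.0, 0.9)

#: P(vividness = 1..5) for simulated trials.
VIVIDNESS_PROBS = (0.01, 0.03, 0.06, 0.35, 0.55)

RATING_SCALES = ("vividness", "detail", "effort", "significance", "valence")


@dataclass(frozen=True)
class GroundTruthProfile:
    """Simulation ground truth: signal amplitude per memory age plus noise model.

    Parameters
    ----------
    amplitudes:
        Signal scaling per time point (arbitrary units, nonnegative); the
        hypothesised consolidation time course.
    shared_component_weight:
        Weight of a retrieval component common to every trial.  It raises
        all pairwise similarities equally and cancels in the
        within-minus-between score.
    noise_sd:
        Marginal standard deviation of the voxel noise (must be > 0).
    spatial_corr_length:
        Gaussian smoothing sigma, in voxels, applied to the white noise.
    """

    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES
    shared_component_weight: float = 0.3
    noise_sd: float = 1.0
    spatial_corr_length: float = 1.5

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if not np.all(np.isfinite(amps)) or np.any(amps < 0):
            raise ValueError("amplitudes must be finite and nonnegative")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticSubject:
    """One simulated participant: schedule, patterns, residuals, ratings, truth."""

    schedule: pd.DataFrame
    patterns: np.ndarray
    residuals: list[np.ndarray]
    vividness: np.ndarray
    truth: GroundTruthProfile
    spec: DesignSpec
    signatures: np.ndarray
    shared_vector: np.ndarray

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.schedule):
            raise ValueError("pattern rows must match schedule rows")
        n_vox = self.patterns.shape[1]
        for r in self.residuals:
            if r.shape[0] < n_vox / 2:
                raise ValueError(
                    "residual matrices need at least voxels/2 rows for "
                    "covariance estimability"
                )

    @property
    def trial_table(self) -> pd.DataFrame:
        """Schedule plus the per-trial vividness rating."""
        out = self.schedule.copy()
        out["vividness"] = self.vividness
        return out


def correlated_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sd: float,
    corr_length: float,
) -> np.ndarray:
    """White noise smoothed along the voxel axis, rescaled to marginal sd."""
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        noise = gaussian_filter1d(noise, sigma=corr_length, axis=1, mode="wrap")
        impulse = np.zeros(shape[1])
        impulse[shape[1] // 2] = 1.0
        kernel = gaussian_filter1d(impulse, sigma=corr_length, mode="wrap")
        noise /= np.sqrt(np.sum(kernel**2))
    return sd * noise


def simulate_subject(
    spec: DesignSpec,
    truth: GroundTruthProfile,
    n_voxels: int,
    seed: int | np.random.Generator,
    scans_per_session: int | None = None,
) -> SyntheticSubject:
    """Simulate one subject's trial patterns, session residuals and ratings.

    Memory signatures are drawn once per memory (unit norm); each trial's
    pattern is the amplitude-scaled signature plus the shared retrieval
    component plus spatially correlated noise.  Deterministic per seed.
    """
    if n_voxels < 8:
        raise ValueError("n_voxels must be >= 8")
    if len(truth.amplitudes) != len(spec.time_points):
        raise ValueError("amplitude profile length must match spec time points")
    rng = np.random.default_rng(seed)
    schedule = build_schedule(spec, rng)

    signatures = rng.standard_normal((spec.n_memories, n_voxels))
    signatures /= np.linalg.norm(signatures, axis=1, keepdims=True)
    shared = rng.standard_normal(n_voxels)
    shared /= np.linalg.norm(shared)

    return _assemble_subject(
        spec, truth, schedule, signatures, shared, rng, scans_per_session
    )


def simulate_followup(
    subject: SyntheticSubject,
    truth2: GroundTruthProfile,
    seed: int | np.random.Generator,
    scans_per_session: int | None = None,
) -> SyntheticSubject:
    """Re-scan the same subject 8 months later.

    Memory signatures (and the shared retrieval vector) are reused so the
    follow-up measures the *same* representations; the schedule, noise and
    ratings are fresh, and signal amplitudes come from ``truth2``, the
    profile at the shifted ages.
    """
    if len(truth2.amplitudes) != len(subject.spec.time_points):
        raise ValueError("truth2 amplitude count does not match the subject's memory set")
    rng = np.random.default_rng(seed)
    schedule = build_schedule(subject.spec, rng)
    return _assemble_subject(
        subject.spec,
        truth2,
        schedule,
        subject.signatures,
        subject.shared_vector,
        rng,
        scans_per_session,
    )


def _assemble_subject(
    spec: DesignSpec,
    truth: GroundTruthProfile,
    schedule: pd.DataFrame,
    signatures: np.ndarray,
    shared: np.ndarray,
    rng: np.random.Generator,
    scans_per_session: int | None,
) -> SyntheticSubject:
    n_voxels = signatures.shape[1]
    amp = dict(zip(spec.time_points, truth.amplitudes))
    noise = correlated_noise(
        rng, (len(schedule), n_voxels), truth.noise_sd, truth.spatial_corr_length
    )
    patterns = np.empty((len(schedule), n_voxels))
    for i, row in enumerate(schedule.itertuples()):
        patterns[i] = (
            amp[row.time_point_months] * signatures[row.memory_id]
            + truth.shared_component_weight * shared
            + noise[i]
        )

    if scans_per_session is None:
        scans_per_session = max(64, -(-n_voxels // 2))
    residuals = [
        correlated_noise(
            rng, (scans_per_session, n_voxels), truth.noise_sd, truth.spatial_corr_length
        )
        for _ in range(spec.n_sessions)
    ]
    vividness = rng.choice(
        np.arange(1, 6), size=len(schedule), p=np.asarray(VIVIDNESS_PROBS)
    )
    return SyntheticSubject(
        schedule=schedule,
        patterns=patterns,
        residuals=residuals,
        vividness=vividness,
        truth=truth,
        spec=spec,
        signatures=signatures,
        shared_vector=shared,
    )


def simulate_cohort(
    n_subjects: int,
    spec: DesignSpec,
    truth: GroundTruthProfile,
    n_voxels: int,
    seed: int,
    scans_per_session: int | None = None,
) -> list[SyntheticSubject]:
    """Independent subjects sharing one design spec and ground truth."""
    root = np.random.default_rng(seed)
    return [
        simulate_subject(spec, truth, n_voxels, root, scans_per_session)
        for _ in range(n_subjects)
    ]


def simulate_ratings_tables(
    n_subjects: int,
    seed: int,
    n_conditions: int = 8,
    covariance: str = "independent",
    n_icc_targets: int = 16,
) -> dict[str, pd.DataFrame]:
    """Behavioural fixtures: subject x condition rating tables and a rater table.

    Returns one subject-by-condition table per 1-5 rating scale (vividness,
    detail, effort, significance, valence) and a two-rater detail-count
    table for interrater-reliability testing.  With
    ``covariance="compound"`` each scale's covariance is compound symmetric
    (subject effect + condition effect + i.i.d. noise), so a downstream
    sphericity estimate should sit near 1.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if covariance not in ("independent", "compound"):
        raise ValueError("covariance must be 'independent' or 'compound'")
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    cols = [f"c{i}" for i in range(n_conditions)]
    for scale in RATING_SCALES:
        cond_means = 3.5 + 0.3 * rng.standard_normal(n_conditions)
        subj = 0.4 * rng.standard_normal((n_subjects, 1))
        noise = 0.4 * rng.standard_normal((n_subjects, n_conditions))
        if covariance == "independent":
            # heterogeneous condition variances break sphericity mildly
            noise *= 0.5 + rng.random(n_conditions)
        values = cond_means + subj + noise
        tables[scale] = pd.DataFrame(
            np.clip(values, 1.0, 5.0), columns=cols,
            index=[f"s{i}" for i in range(n_subjects)],
        )
    true_counts = rng.poisson(30, size=n_icc_targets).astype(float)
    rater1 = true_counts + rng.normal(0, 3, n_icc_targets)
    rater2 = true_counts + rng.normal(0, 3, n_icc_targets)
    tables["icc_details"] = pd.DataFrame(
        {"rater1": np.round(rater1), "rater2": np.round(rater2)}
    )
    return tables
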