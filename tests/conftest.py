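import numpy as np
import pandas as pd
import pytest

from memtrace.design import DesignSpec
from memtrace.simulate import GroundTruthProfile, simulate_subject


@pytest.fixture(scope="session")
def spec() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def high_snr_truth() -> GroundTruthProfile:
    """Low-noise ground truth for recovery-style checks."""
    return GroundTruthProfile(noise_sd=0.25)


@pytest.fixture(scope="session")
def small_subject(spec, high_snr_truth):
    """One simulated subject with few voxels, reused across read-only tests."""
    return simulate_subject(spec, high_snr_truth, n_voxels=48, seed=7)


def toy_trials(memory_ids, sessions, time_points=None, sets=None) -> pd.DataFrame:
    """Hand-built trial tables for oracle tests."""
    n = len(memory_ids)
    tps = time_points if time_points is not None else [float(m) for m in memory_ids]
    sets_ = sets if sets is not None else ["A"] * n
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "session": sessions,
            "memory_id": memory_ids,
            "time_point_months": tps,
            "set": sets_,
            "order": np.zeros(n, dtype=int),
        }
    )
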