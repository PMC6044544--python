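"""Representation scores: filtering, similarity oracles, RSM diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtrace.rsa import (
    between_memory_profile,
    cross_session_similarity,
    filter_vivid_trials,
    group_rsm,
    memory_rsm,
    MemoryRSM,
    neural_representation_score,
    timepoint_scores,
)
from tests.conftest import toy_trials


def pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def brute_force_rsm(patterns, trials):
    """Independent pairwise-enumeration oracle for the memory RSM."""
    ids = sorted(trials["memory_id"].unique())
    out = np.full((len(ids), len(ids)), np.nan)
    for ia, ma in enumerate(ids):
        for ib, mb in enumerate(ids):
            vals = []
            rows_a = trials.index[trials["memory_id"] == ma]
            rows_b = trials.index[trials["memory_id"] == mb]
            for i, j in itertools.product(rows_a, rows_b):
                if ma == mb and i >= j:
                    continue
                if trials.loc[i, "session"] == trials.loc[j, "session"]:
                    continue
                vals.append(pearson(patterns[i], patterns[j]))
            if vals:
                out[ia, ib] = np.mean(vals)
    return out


class TestFiltering:
    def test_threshold_one_is_identity(self, small_subject):
        res = filter_vivid_trials(small_subject.trial_table, threshold=1)
        assert len(res.trials) == len(small_subject.trial_table)
        assert res.unscorable == ()

    def test_direct_count_example(self):
        trials = toy_trials([0] * 6, [1, 2, 3, 4, 5, 6])
        trials["vividness"] = [5, 5, 5, 4, 4, 2]
        res = filter_vivid_trials(trials, threshold=3)
        assert len(res.trials) == 5
        assert res.unscorable == ()

    def test_threshold_six_flags_everything(self, small_subject):
        res = filter_vivid_trials(small_subject.trial_table, threshold=6)
        assert set(res.unscorable) == set(
            small_subject.trial_table["memory_id"].unique()
        )

    def test_memory_needs_two_sessions(self):
        trials = toy_trials([0, 0, 0], [1, 1, 1])
        trials["vividness"] = [5, 5, 5]
        res = filter_vivid_trials(trials, threshold=3)
        assert res.unscorable == (0,)

    def test_invalid_vividness_rejected(self):
        trials = toy_trials([0, 0], [1, 2])
        trials["vividness"] = [5, 7]
        with pytest.raises(ValueError, match="1..5"):
            filter_vivid_trials(trials)


class TestSimilarity:
    def test_identical_trials_give_one(self):
        pat = np.tile([1.0, 2.0, 4.0], (3, 1))
        trials = toy_trials([0, 0, 0], [1, 2, 3])
        assert cross_session_similarity(pat, trials, 0, 0) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        pat = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        trials = toy_trials([0, 1], [1, 2])
        assert cross_session_similarity(pat, trials, 0, 1) == pytest.approx(-1.0)

    def test_brute_force_pairwise_oracle(self):
        pat = np.array(
            [[1, 2, 5], [2, 1, 7], [4, 2, 2], [1, 5, 3], [2, 2, 9]], dtype=float
        )
        trials = toy_trials([0, 0, 0, 1, 1], [1, 2, 3, 1, 2])
        expected = np.mean(
            [
                pearson(pat[i], pat[j])
                for i, j in [(0, 4), (1, 3), (2, 3), (2, 4)]
                + [(0, 3)][:0]  # (0,3) same session: excluded
            ]
        )
        # eligible cross-session pairs: (0,4),(1,3),(2,3),(2,4) — (0,3) and
        # (1,4) share sessions 1 and 2 respectively
        got = cross_session_similarity(pat, trials, 0, 1)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_eligible_pairs_errors(self):
        pat = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 1.0]])
        trials = toy_trials([0, 1], [1, 1])
        with pytest.raises(ValueError, match="no eligible"):
            cross_session_similarity(pat, trials, 0, 1)

    def test_zero_variance_trial_errors(self):
        pat = np.array([[1.0, 1.0, 1.0], [3.0, 1.0, 2.0]])
        trials = toy_trials([0, 0], [1, 2])
        with pytest.raises(ValueError, match="zero-variance"):
            cross_session_similarity(pat, trials, 0, 0)


class TestScores:
    def test_all_memories_identical_pattern_scores_zero(self):
        pat = np.tile([1.0, 3.0, 2.0], (8, 1))
        trials = toy_trials(
            [0, 0, 1, 1, 2, 2, 3, 3],
            [1, 2, 1, 2, 1, 2, 1, 2],
            time_points=[1.0, 1.0, 2.0, 2.0, 1.0, 1.0, 2.0, 2.0],
            sets=["A", "A", "A", "A", "B", "B", "B", "B"],
        )
        for variant in ("all-other", "matched-age"):
            assert neural_representation_score(pat, trials, 0, variant) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_orthogonal_signature_scores_one(self):
        # mean-zero orthogonal vectors: within = 1, between = 0
        sig = {0: [1.0, -1.0, 1.0, -1.0], 1: [1.0, 1.0, -1.0, -1.0]}
        pat = np.array([sig[0], sig[0], sig[1], sig[1]])
        trials = toy_trials([0, 0, 1, 1], [1, 2, 1, 2])
        assert neural_representation_score(pat, trials, 0) == pytest.approx(1.0)

    def test_brute_force_oracle_small_instance(self):
        rng = np.random.default_rng(0)
        pat = rng.integers(-5, 6, size=(8, 3)).astype(float)
        trials = toy_trials(
            [0, 0, 1, 1, 2, 2, 3, 3],
            [1, 2, 2, 3, 1, 3, 1, 2],
        )
        rsm = memory_rsm(pat, trials)
        oracle = brute_force_rsm(pat, trials)
        assert np.allclose(rsm.matrix, oracle, atol=1e-12, equal_nan=True)
        for mid in range(4):
            i = mid
            expected = oracle[i, i] - np.mean(np.delete(oracle[i], i))
            got = neural_representation_score(pat, trials, mid)
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
    )
    def test_score_invariant_to_global_affine_rescaling(self, scale, offset):
        rng = np.random.default_rng(1)
        pat = rng.standard_normal((8, 5))
        trials = toy_trials([0, 0, 1, 1, 2, 2, 3, 3], [1, 2, 2, 3, 1, 3, 1, 2])
        base = neural_representation_score(pat, trials, 1)
        moved = neural_representation_score(scale * pat + offset, trials, 1)
        assert moved == pytest.approx(base, abs=1e-9)


class TestTimepointScores:
    def test_mean_of_two_memories(self):
        # construct two memories at one age whose scores differ
        sig = {0: [1.0, -1.0, 1.0, -1.0], 1: [1.0, 1.0, -1.0, -1.0]}
        pat = np.array([sig[0], sig[0], sig[1], sig[1]], dtype=float)
        trials = toy_trials(
            [0, 0, 1, 1],
            [1, 2, 1, 2],
            time_points=[3.0, 3.0, 3.0, 3.0],
            sets=["A", "A", "B", "B"],
        )
        out = timepoint_scores(pat, trials, variant="matched-age")
        a = neural_representation_score(pat, trials, 0, "matched-age")
        b = neural_representation_score(pat, trials, 1, "matched-age")
        assert out.loc[3.0, "score"] == pytest.approx((a + b) / 2)

    def test_unscorable_memory_flagged_and_other_used(self, spec, high_snr_truth):
        from memtrace.simulate import simulate_subject

        subj = simulate_subject(spec, high_snr_truth, 32, seed=5, scans_per_session=16)
        unscorable = (1,)  # memory 1 is set A, age 4 months
        out = timepoint_scores(subj.patterns, subj.schedule, unscorable=unscorable)
        assert out.loc[4.0, "incomplete"]
        assert out.loc[4.0, "n_memories"] == 1
        assert out.loc[4.0, "score"] == pytest.approx(out.loc[4.0, "score_B"])

    def test_per_set_profiles_replicate_at_high_snr(self, spec):
        from memtrace.rsa import stack_scores
        from memtrace.simulate import GroundTruthProfile, simulate_subject
        from scipy.stats import spearmanr

        truth = GroundTruthProfile(noise_sd=0.35)
        rhos = []
        for seed in range(20):
            frames = []
            for s in range(6):
                subj = simulate_subject(
                    spec, truth, 64, seed=1000 * seed + s, scans_per_session=32
                )
                frames.append(timepoint_scores(subj.patterns, subj.schedule))
            a = stack_scores(frames, "score_A").mean(axis=0)
            b = stack_scores(frames, "score_B").mean(axis=0)
            rhos.append(spearmanr(a, b).statistic)
        assert np.mean(rhos) > 0.6


class TestGroupRSM:
    def _toy_rsm(self, values):
        labels = pd.DataFrame(
            {
                "memory_id": [0, 1],
                "time_point_months": [1.0, 2.0],
                "set": ["A", "A"],
            }
        )
        return MemoryRSM(matrix=np.asarray(values, float), labels=labels)

    def test_single_subject_no_display_is_identity(self):
        rsm = self._toy_rsm([[0.5, 0.2], [0.2, 0.4]])
        out = group_rsm([rsm], display=False)
        assert np.allclose(out.matrix, rsm.matrix)

    def test_rank_transform_by_hand(self):
        rsm = self._toy_rsm([[0.1, 0.3], [0.3, 0.9]])
        out = group_rsm([rsm], display=True)
        assert np.allclose(out.matrix, [[0.0, 0.5], [0.5, 1.0]])

    def test_display_range_bounds(self):
        rsm = self._toy_rsm([[0.5, 0.1], [0.1, 0.8]])
        out = group_rsm([rsm], display=True)
        assert out.matrix.min() == 0.0
        assert out.matrix.max() == 1.0

    def test_label_mismatch_rejected(self):
        a = self._toy_rsm([[0.5, 0.1], [0.1, 0.8]])
        b = self._toy_rsm([[0.5, 0.1], [0.1, 0.8]])
        b.labels = b.labels.assign(memory_id=[0, 2])
        with pytest.raises(ValueError, match="labels"):
            group_rsm([a, b])


class TestBetweenMemoryProfile:
    def test_single_subject_hand_average(self):
        labels = pd.DataFrame(
            {
                "memory_id": [0, 1, 2, 3],
                "time_point_months": [1.0, 2.0, 1.0, 2.0],
                "set": ["A", "A", "B", "B"],
            }
        )
        m = np.array(
            [
                [0.9, 0.1, 0.2, 0.3],
                [0.1, 0.8, 0.4, 0.5],
                [0.2, 0.4, 0.7, 0.6],
                [0.3, 0.5, 0.6, 0.95],
            ]
        )
        prof = between_memory_profile([MemoryRSM(matrix=m, labels=labels)])
        # age 1: memories 0 (baseline .1) and 2 (baseline .6); age 2: 1 (.1), 3 (.6)
        assert prof.loc[0, 1.0] == pytest.approx((0.1 + 0.6) / 2)
        assert prof.loc[0, 2.0] == pytest.approx((0.1 + 0.6) / 2)

    def test_shared_component_elevates_profile_not_score(self, spec):
        from memtrace.simulate import GroundTruthProfile, simulate_subject

        plain = GroundTruthProfile(shared_component_weight=0.0, noise_sd=0.5)
        shared = GroundTruthProfile(shared_component_weight=2.0, noise_sd=0.5)
        profs, scores = {}, {}
        for truth in (plain, shared):
            p_list, s_list = [], []
            for seed in range(8):
                subj = simulate_subject(
                    spec, truth, 48, seed=seed, scans_per_session=24
                )
                rsm = memory_rsm(subj.patterns, subj.schedule)
                p_list.append(between_memory_profile([rsm]).to_numpy().mean())
                s_list.append(
                    timepoint_scores(subj.patterns, subj.schedule)["score"].mean()
                )
            profs[truth.shared_component_weight] = np.mean(p_list)
            scores[truth.shared_component_weight] = np.mean(s_list)
        assert profs[2.0] > profs[0.0] + 0.2
        assert scores[2.0] == pytest.approx(scores[0.0], abs=0.05)
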