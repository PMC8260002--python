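"""Arrangement geometry, inverse-MDS estimation and adaptive sessions."""

import numpy as np
import pytest

from semrdm.arrangement import (
    InverseMDS,
    run_session,
    select_next_subset,
    trial_distances,
    update_estimate,
)
from semrdm.synthetic import planar_word_rdm, simulated_subject_place
from semrdm.stats import rank_correlation, rdm_correlation
from semrdm.types import ArrangementTrial, DissimilarityMatrix, EvidenceState


def make_trial(index, words, positions):
    return ArrangementTrial(trial_index=index, words=list(words),
                            positions=np.asarray(positions, dtype=float))


class TestTrialGeometry:
    def test_three_four_five_triangle(self):
        trial = make_trial(0, "abc", [[0, 0], [0.3, 0], [0.3, 0.4]])
        d = trial_distances(trial)
        assert d[0, 1] == pytest.approx(0.3)
        assert d[1, 2] == pytest.approx(0.4)
        assert d[0, 2] == pytest.approx(0.5)

    def test_antipodal_rim_distance_is_arena_diameter(self):
        trial = make_trial(0, "ab", [[-0.5, 0], [0.5, 0]])
        assert trial_distances(trial)[0, 1] == pytest.approx(1.0)

    def test_coincident_words_allowed(self):
        trial = make_trial(0, "ab", [[0.1, 0.1], [0.1, 0.1]])
        assert trial_distances(trial)[0, 1] == 0.0

    def test_duplicate_word_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_trial(0, ["a", "a"], [[0, 0], [0.1, 0]])

    def test_positions_outside_arena_rejected(self):
        with pytest.raises(ValueError, match="arena"):
            make_trial(0, "ab", [[0.6, 0.0], [0, 0]])


class TestUpdateEstimate:
    def test_single_trial_closed_form(self):
        trial = make_trial(0, "abc", [[0, 0], [0.3, 0], [0.3, 0.4]])
        state = update_estimate([trial])
        d = trial_distances(trial)
        np.testing.assert_allclose(state.estimate.values, d, atol=1e-9)
        np.testing.assert_allclose(state.evidence, d**2, atol=1e-9)

    def test_two_scaled_trials_fit_scales_in_ratio(self):
        """Trial 2 at half the spread of trial 1: scales converge to ratio 2:1
        and the combined estimate is rank-identical to either trial."""
        big = np.array([[0.0, 0.0], [0.4, 0.0], [0.1, 0.3], [-0.3, -0.2]])
        t1 = make_trial(0, "abcd", big)
        t2 = make_trial(1, "abcd", big / 2)
        state = update_estimate([t1, t2], tol=1e-10)
        s1, s2 = state.trial_scales
        assert s2 / s1 == pytest.approx(2.0, abs=1e-6)
        d1 = trial_distances(t1)
        iu = np.triu_indices(4, k=1)
        assert rank_correlation(state.estimate.values[iu], d1[iu]) == 1.0

    def test_evidence_accumulates_multiplicatively(self):
        """Two co-arrangements at w=0.5 each give E = 1 - 0.25 = 0.75."""
        d = np.sqrt(0.5)
        pos = [[-d / 2, 0.0], [d / 2, 0.0]]
        trials = [make_trial(i, "ab", pos) for i in range(2)]
        state = update_estimate(trials)
        assert state.evidence[0, 1] == pytest.approx(0.75, abs=1e-12)

    def test_never_coarranged_pair_is_missing(self):
        t1 = make_trial(0, "abc", [[0, 0], [0.3, 0], [0, 0.3]])
        t2 = make_trial(1, "abd", [[0, 0], [0.3, 0], [0, 0.4]])
        state = update_estimate([t1, t2], labels=list("abcd"))
        i, j = 2, 3  # c and d never co-arranged
        assert np.isnan(state.estimate.values[i, j])
        assert state.evidence[i, j] == 0.0

    def test_estimate_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.3, 0.3, size=(6, 2))
        t1 = make_trial(0, "abcdef", pts)
        t2 = make_trial(1, "abcdef", pts * 0.5)
        base = update_estimate([t1, t2]).estimate
        scaled = update_estimate(
            [make_trial(0, "abcdef", pts * 0.8),
             make_trial(1, "abcdef", pts * 0.4)]
        ).estimate
        assert rdm_correlation(base, scaled) == pytest.approx(1.0)

    def test_estimator_exposes_sklearn_params(self):
        est = InverseMDS(tol=1e-8, max_iter=50)
        assert est.get_params() == {"tol": 1e-8, "max_iter": 50}


class TestSubsetSelection:
    def _state(self, evidence, labels):
        n = len(labels)
        est = DissimilarityMatrix(labels, np.zeros((n, n)), metric="behavioral")
        return EvidenceState(estimate=est, evidence=np.asarray(evidence, float),
                             trial_scales=[1.0])

    def test_seeds_with_weakest_pair(self):
        E = np.array(
            [
                [0.0, 0.9, 0.8, 0.7],
                [0.9, 0.0, 0.2, 0.9],
                [0.8, 0.2, 0.0, 0.9],
                [0.7, 0.9, 0.9, 0.0],
            ]
        )
        subset = select_next_subset(self._state(E, list("abcd")), 3)
        assert subset[:2] == ["b", "c"]

    def test_greedy_matches_exhaustive_deficit_ranking(self):
        rng = np.random.default_rng(1)
        E = rng.uniform(0.1, 0.9, size=(5, 5))
        E = (E + E.T) / 2
        np.fill_diagonal(E, 0.0)
        labels = list("abcde")
        state = self._state(E, labels)
        subset = select_next_subset(state, 4)
        # brute-force replay of the greedy rule
        iu = np.triu_indices(5, k=1)
        i, j = iu[0][np.argmin(E[iu])], iu[1][np.argmin(E[iu])]
        chosen = [i, j]
        while len(chosen) < 4:
            cands = [k for k in range(5) if k not in chosen]
            deficits = [(1 - E[k, chosen]).sum() for k in cands]
            chosen.append(cands[int(np.argmax(deficits))])
        assert subset == [labels[k] for k in chosen]

    def test_subset_size_bounds(self):
        state = self._state(np.zeros((4, 4)), list("abcd"))
        with pytest.raises(ValueError):
            select_next_subset(state, 2)
        with pytest.raises(ValueError):
            select_next_subset(state, 61)


class TestRunSession:
    def test_immediate_stop_when_first_trial_suffices(self):
        """An equilateral rim placement gives w = 0.75 on every pair; with a
        lower threshold the session ends after the single full-set trial."""
        r = 0.5
        angles = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        pos = np.c_[r * np.cos(angles), r * np.sin(angles)]

        state, trials = run_session(
            ["a", "b", "c"], lambda subset, seed: pos[: len(subset)],
            evidence_threshold=0.5, max_trials=10, subset_size=3, seed=0,
        )
        assert len(trials) == 1
        assert state.min_evidence() == pytest.approx(0.75, abs=1e-9)

    def test_single_trial_cannot_exceed_default_threshold(self):
        """Geometry caps single-trial evidence at 0.75 for >= 3 words, so the
        default 0.75 rule always requires at least two trials."""
        r = 0.5
        angles = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        pos = np.c_[r * np.cos(angles), r * np.sin(angles)]
        state, trials = run_session(
            ["a", "b", "c"], lambda subset, seed: pos[: len(subset)],
            evidence_threshold=0.75, max_trials=3, subset_size=3, seed=0,
        )
        assert len(trials) >= 2

    def test_evidence_nondecreasing_and_termination(self):
        truth = planar_word_rdm(12, seed=3)
        evidences = []

        def place(subset, seed):
            return simulated_subject_place(truth, subset, 0.02, seed)

        state, trials = run_session(
            truth.labels, place, max_trials=8, subset_size=6, seed=5
        )
        assert len(trials) <= 8
        # replay incrementally: per-pair evidence never decreases
        prev = np.zeros((12, 12))
        for k in range(1, len(trials) + 1):
            ev = update_estimate(trials[:k], labels=truth.labels).evidence
            assert np.all(ev >= prev - 1e-12)
            prev = ev

    def test_noiseless_planar_truth_recovered(self):
        truth = planar_word_rdm(12, seed=1)
        state, _ = run_session(
            truth.labels,
            lambda subset, seed: simulated_subject_place(truth, subset, 0.0, seed),
            max_trials=6, subset_size=6, seed=2,
        )
        assert rdm_correlation(truth, state.estimate) >= 0.99

    def test_invalid_callback_positions_reported_with_trial(self):
        def bad_place(subset, seed):
            return np.full((len(subset), 2), 5.0)

        with pytest.raises(ValueError, match="trial 0"):
            run_session(["a", "b", "c"], bad_place, max_trials=2, seed=0)
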