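"""Multi-arrangement behavioral engine (inverse multidimensional scaling).

Participants drag words into a circular arena; on-screen inter-word distances
(in arena-diameter units, so the maximum is 1) encode judged dissimilarity.
The first trial arranges the full word set; later trials arrange adaptively
chosen subsets. A full dissimilarity matrix is estimated from the partial
arrangements by alternating two steps until convergence: each trial gets a
least-squares scale factor (through the origin — zero dissimilarity must map
to zero distance) aligning its distances to the current global estimate, and
the global estimate is recomputed as the evidence-weighted average of the
scale-adjusted trial distances. The evidence weight of a pair within a trial
is its squared normalized screen distance — larger separations are more
reliable relative to motor and conceptual placement noise — and evidence
accumulates across trials as ``E = 1 - prod(1 - w)``, staying in [0, 1]. A
session ends when every pair's evidence exceeds a threshold (0.75) or a trial
budget standing in for the 1-hour session clock runs out.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .types import (
    ArrangementTrial,
    DissimilarityMatrix,
    EvidenceState,
    SubjectCallback,
)

logger = logging.getLogger(__name__)

__all__ = [
    "trial_distances",
    "InverseMDS",
    "update_estimate",
    "select_next_subset",
    "run_session",
]


def trial_distances(trial: ArrangementTrial) -> np.ndarray:
    """Pairwise Euclidean screen distances (n-by-n, arena-diameter units)."""
    diff = trial.positions[:, None, :] - trial.positions[None, :, :]
    return np.linalg.norm(diff, axis=-1)


class InverseMDS(BaseEstimator):
    """Evidence-weighted dissimilarity estimator for arrangement trials.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the largest change of any estimate entry
        between alternating-refinement sweeps.
    max_iter : int
        Cap on refinement sweeps.

    Fitted attributes: ``estimate_`` (behavioral
    :class:`~semrdm.types.DissimilarityMatrix`; never-co-arranged pairs are
    NaN), ``evidence_`` (P-by-P in [0, 1]), ``trial_scales_`` and ``n_iter_``.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, trials: Sequence[ArrangementTrial], labels: Sequence[str] | None = None):
        if not trials:
            raise ValueError("need at least one trial")
        if labels is None:
            labels = []
            seen: set[str] = set()
            for t in trials:
                for w in t.words:
                    if w not in seen:
                        seen.add(w)
                        labels.append(w)
        labels = list(labels)
        index = {w: i for i, w in enumerate(labels)}
        P = len(labels)

        per_trial = []  # (index array, distance matrix, weight matrix)
        for t in trials:
            try:
                idx = np.array([index[w] for w in t.words])
            except KeyError as exc:
                raise ValueError(f"trial word {exc} not in label set") from None
            d = trial_distances(t)
            per_trial.append((idx, d, np.clip(d**2, 0.0, 1.0)))

        seen_pair = np.zeros((P, P), dtype=bool)
        for idx, _, _ in per_trial:
            seen_pair[np.ix_(idx, idx)] = True
        np.fill_diagonal(seen_pair, False)

        def weighted_average(scales: np.ndarray) -> np.ndarray:
            num = np.zeros((P, P))
            den = np.zeros((P, P))
            for (idx, d, w), s in zip(per_trial, scales):
                ix = np.ix_(idx, idx)
                num[ix] += w * (s * d)
                den[ix] += w
            with np.errstate(invalid="ignore"):
                est = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            # co-arranged pairs judged identical everywhere: distance 0
            est[seen_pair & (den == 0)] = 0.0
            est[~seen_pair] = np.nan
            np.fill_diagonal(est, 0.0)
            return est

        # initialize from the first trial alone, scale 1
        scales = np.ones(len(per_trial))
        idx0, d0, _ = per_trial[0]
        estimate = np.full((P, P), np.nan)
        estimate[np.ix_(idx0, idx0)] = d0
        estimate[~seen_pair] = np.nan
        np.fill_diagonal(estimate, 0.0)

        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            new_scales = np.empty_like(scales)
            for ti, (idx, d, _) in enumerate(per_trial):
                sub = estimate[np.ix_(idx, idx)]
                mask = np.isfinite(sub)
                np.fill_diagonal(mask, False)
                denom = float((d[mask] ** 2).sum())
                new_scales[ti] = (
                    float((d[mask] * sub[mask]).sum()) / denom if denom > 0 else 1.0
                )
            new_estimate = weighted_average(new_scales)
            both = np.isfinite(estimate) & np.isfinite(new_estimate)
            delta = float(np.abs(new_estimate[both] - estimate[both]).max()) if both.any() else 0.0
            estimate, scales = new_estimate, new_scales
            if delta < self.tol:
                break

        no_evidence = np.ones((P, P))
        for idx, _, w in per_trial:
            ix = np.ix_(idx, idx)
            no_evidence[ix] = no_evidence[ix] * (1.0 - w)
        evidence = np.clip(1.0 - no_evidence, 0.0, 1.0)
        np.fill_diagonal(evidence, 0.0)

        self.labels_ = labels
        self.estimate_ = DissimilarityMatrix(
            labels=labels, values=estimate, metric="behavioral"
        )
        self.evidence_ = evidence
        self.trial_scales_ = [float(s) for s in scales]
        self.n_iter_ = n_iter
        return self

    def state(self) -> EvidenceState:
        return EvidenceState(
            estimate=self.estimate_,
            evidence=self.evidence_,
            trial_scales=self.trial_scales_,
            n_iterations=self.n_iter_,
        )


def update_estimate(
    trials: Sequence[ArrangementTrial],
    tol: float = 1e-6,
    max_iter: int = 100,
    labels: Sequence[str] | None = None,
) -> EvidenceState:
    """Estimate the dissimilarity matrix and pairwise evidence from trials."""
    return InverseMDS(tol=tol, max_iter=max_iter).fit(trials, labels=labels).state()


def select_next_subset(
    state: EvidenceState, subset_size: int, max_words: int = 60
) -> list[str]:
    """Greedy weakest-evidence subset for the next trial.

    The subset is seeded with the two words of the minimum-evidence pair; each
    following word maximizes the summed evidence deficit (1 - E) over pairs it
    forms with the current subset. Ties break by label order.
    """
    labels = state.estimate.labels
    P = len(labels)
    if subset_size < 3:
        raise ValueError("subset_size must be >= 3")
    if subset_size > max_words:
        raise ValueError(f"subset_size exceeds the {max_words}-word trial cap")
    subset_size = min(subset_size, P)

    E = state.evidence
    iu = np.triu_indices(P, k=1)
    order = np.argmin(E[iu])  # row-major upper triangle: lowest (i, j) wins ties
    i, j = iu[0][order], iu[1][order]
    chosen = [int(i), int(j)]
    remaining = [k for k in range(P) if k not in chosen]
    while len(chosen) < subset_size:
        deficits = np.array([(1.0 - E[k, chosen]).sum() for k in remaining])
        best = int(np.argmax(deficits))  # first max: lowest index = label order
        chosen.append(remaining.pop(best))
    return [labels[k] for k in chosen]


def run_session(
    words: Sequence[str],
    place: SubjectCallback,
    evidence_threshold: float = 0.75,
    max_trials: int = 25,
    subset_size: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[EvidenceState, list[ArrangementTrial]]:
    """Run an adaptive arrangement session against a subject callback.

    Trial 1 presents the full word set; subsequent trials use
    :func:`select_next_subset`. After each trial the estimate and evidence are
    refreshed; the session stops once the minimum pairwise evidence exceeds
    ``evidence_threshold`` or after ``max_trials`` trials (the budget stands in
    for the 1-hour wall clock). Returns the final state and the trial log.
    """
    words = list(words)
    if len(words) < 3:
        raise ValueError("need at least 3 words")
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    rng = np.random.default_rng(seed)

    def make_trial(trial_index: int, subset: list[str]) -> ArrangementTrial:
        trial_seed = int(rng.integers(2**31))
        positions = np.asarray(place(subset, trial_seed), dtype=float)
        try:
            return ArrangementTrial(
                trial_index=trial_index, words=subset, positions=positions
            )
        except ValueError as exc:
            raise ValueError(f"invalid positions on trial {trial_index}: {exc}") from exc

    trials = [make_trial(0, words)]
    state = update_estimate(trials, tol=tol, max_iter=max_iter, labels=words)
    while state.min_evidence() <= evidence_threshold and len(trials) < max_trials:
        subset = select_next_subset(state, min(subset_size, len(words)))
        trials.append(make_trial(len(trials), subset))
        state = update_estimate(trials, tol=tol, max_iter=max_iter, labels=words)
    return state, trials
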