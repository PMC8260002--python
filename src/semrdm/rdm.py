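"""Word dissimilarity matrices from encoding models and embeddings.

A brain-derived RDM is built in four steps: the fitted (K * n_delays)-by-N
weights are collapsed to K-by-N by averaging across the hemodynamic delay
blocks; a voxel set is chosen (all voxels, the top M by prediction accuracy,
or one anatomical region); the task words' K-dimensional vectors are projected
through the collapsed weights into the modeled voxel space; and the pairwise
correlation distance (1 - Pearson r) of the projected representations forms
the matrix. Applying the correlation distance directly to raw embedding rows
gives the word-vector-derived RDM; for binary-occurrence models the collapsed
weight rows are themselves the word representations.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AccuracyProfile, DissimilarityMatrix, EncodingModel

logger = logging.getLogger(__name__)

__all__ = [
    "collapse_delays",
    "select_voxels",
    "project_words",
    "correlation_distance_rdm",
    "average_rdms",
    "subset_rdm",
    "read_rdm",
    "write_rdm",
]


def collapse_delays(model: EncodingModel) -> np.ndarray:
    """Average the per-delay weight blocks down to a K-by-N matrix."""
    L = len(model.delays)
    K = model.n_features
    return model.weights.reshape(L, K, model.n_voxels).mean(axis=0)


def select_voxels(profile: AccuracyProfile, mode: str, m_or_region=None) -> np.ndarray:
    """Voxel index set: ``all``, ``top_m`` by accuracy, or one region.

    Top-M ties are broken toward the lower voxel index for reproducibility.
    Indices are returned in ascending order.
    """
    n = profile.n_voxels
    if mode == "all":
        return np.arange(n)
    if mode == "top_m":
        m = int(m_or_region)
        if m < 1:
            raise ValueError("m must be >= 1")
        if m > n:
            raise ValueError(f"m={m} exceeds {n} voxels")
        order = np.lexsort((np.arange(n), -profile.per_voxel_r))
        return np.sort(order[:m])
    if mode == "region":
        if profile.region_labels is None:
            raise ValueError("profile carries no region labels")
        idx = np.flatnonzero(profile.region_labels == m_or_region)
        if idx.size == 0:
            raise ValueError(f"no voxels in region {m_or_region!r}")
        return idx
    raise ValueError("mode must be 'all', 'top_m' or 'region'")


def project_words(
    word_vectors: np.ndarray, weights: np.ndarray, voxel_set=None
) -> np.ndarray:
    """Project P-by-K word vectors through K-by-N collapsed weights.

    Returns P-by-|voxel_set| word representations in the modeled brain space.
    For binary-occurrence models pass the identity as ``word_vectors`` (the
    collapsed weight rows are the representations).
    """
    word_vectors = np.asarray(word_vectors, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if word_vectors.shape[1] != weights.shape[0]:
        raise ValueError(
            f"word vectors have {word_vectors.shape[1]} dims but weights have "
            f"{weights.shape[0]} rows"
        )
    reps = word_vectors @ weights
    if voxel_set is not None:
        reps = reps[:, np.asarray(voxel_set, dtype=int)]
    return reps


def correlation_distance_rdm(
    representations: np.ndarray, labels: Sequence[str]
) -> DissimilarityMatrix:
    """Pairwise correlation distance (1 - Pearson r) between representation rows."""
    reps = np.asarray(representations, dtype=float)
    if reps.ndim != 2 or reps.shape[0] != len(labels):
        raise ValueError("representations must have one row per label")
    if reps.shape[1] < 3:
        raise ValueError("need representation dimension >= 3")
    flat = np.flatnonzero(reps.std(axis=1) == 0)
    if flat.size:
        raise ValueError(
            f"word {labels[int(flat[0])]!r} has a zero-variance representation"
        )
    corr = np.corrcoef(reps)
    values = 1.0 - corr
    values = np.clip((values + values.T) / 2, 0.0, 2.0)
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(labels=list(labels), values=values,
                               metric="correlation_distance")


def average_rdms(rdms: Sequence[DissimilarityMatrix]) -> DissimilarityMatrix:
    """Elementwise mean of RDMs with identical labels (participant averaging)."""
    if not rdms:
        raise ValueError("no RDMs to average")
    first = rdms[0]
    for other in rdms[1:]:
        if other.labels != first.labels:
            raise ValueError("RDM labels differ; cannot average")
        if other.metric != first.metric:
            raise ValueError("RDM metrics differ; cannot average")
    mean = np.mean([r.values for r in rdms], axis=0)
    if first.metric == "correlation_distance":
        mean = np.clip(mean, 0.0, 2.0)
        np.fill_diagonal(mean, 0.0)
    return DissimilarityMatrix(labels=list(first.labels), values=mean,
                               metric=first.metric)


def subset_rdm(rdm: DissimilarityMatrix, keep: Sequence[str]) -> DissimilarityMatrix:
    """Principal submatrix for the labels in ``keep``, in that order."""
    keep = list(keep)
    if len(keep) < 3:
        raise ValueError("need at least 3 labels")
    missing = [w for w in keep if w not in rdm.index]
    if missing:
        raise ValueError(f"unknown labels: {missing}")
    idx = np.array([rdm.index[w] for w in keep])
    return DissimilarityMatrix(labels=keep, values=rdm.values[np.ix_(idx, idx)],
                               metric=rdm.metric)


def intersect_rdms(
    rdm_a: DissimilarityMatrix, rdm_b: DissimilarityMatrix
) -> tuple[DissimilarityMatrix, DissimilarityMatrix]:
    """Restrict both RDMs to their shared labels (order of ``rdm_a``).

    Words absent from one vocabulary are dropped with a warning (occurrence
    models typically cover only part of the task word set).
    """
    shared = [w for w in rdm_a.labels if w in rdm_b.index]
    dropped = len(rdm_a.labels) + len(rdm_b.labels) - 2 * len(shared)
    if dropped:
        logger.warning("dropping %d non-shared labels from RDM comparison", dropped)
    return subset_rdm(rdm_a, shared), subset_rdm(rdm_b, shared)


# ---------------------------------------------------------------------------
# CSV I/O (square matrix with a label header row and column)
# ---------------------------------------------------------------------------

def write_rdm(rdm: DissimilarityMatrix, path) -> None:
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, float_format="%.12g")


def read_rdm(path, metric: str = "correlation_distance") -> DissimilarityMatrix:
    """Read a square label-headed CSV; symmetry and zero diagonal are validated."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(w) for w in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    if np.nanmax(np.abs(values - values.T), initial=0.0) > 1e-6:
        raise ValueError(f"{path}: matrix is asymmetric beyond 1e-6")
    values = (values + values.T) / 2
    return DissimilarityMatrix(labels=labels, values=values, metric=metric)
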