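"""Synthetic ground truth for end-to-end parameter-recovery testing.

The real study's fMRI recordings are not available, so every downstream stage
is exercised against simulated data with planted structure: a category-
structured word embedding (six categories of ten nouns, mirroring the task
vocabulary), annotator description streams whose scene vectors follow the
two-level averaging rule, voxel responses generated as delay-embedded linear
projections of the scene vectors plus isotropic Gaussian noise, and simulated
participants who arrange word subsets by noisily embedding the true
dissimilarity structure into the 2-D arena. All generators are deterministic
under their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import features as _features
from .encoding import DEFAULT_DELAYS, delay_embed
from .rdm import subset_rdm
from .types import (
    ARENA_RADIUS,
    DissimilarityMatrix,
    EmbeddingSpace,
    ResponseSeries,
    SceneDescription,
    SceneFeatureSeries,
)
from .wordsets import TASK_NOUNS

__all__ = [
    "DEFAULT_DELAY_GAINS",
    "SyntheticGroundTruth",
    "movie_schedule",
    "make_embedding_truth",
    "make_scene_stream",
    "make_brain_truth",
    "simulate_responses",
    "simulated_subject_place",
    "planar_word_rdm",
]

#: Per-delay gains applied to the planted weights, a crude hemodynamic
#: envelope peaking at the middle delays. Any positive profile supports
#: recovery tests; this one is fixed for reproducibility.
DEFAULT_DELAY_GAINS: tuple[float, ...] = (0.4, 0.8, 0.8, 0.4)


@dataclass
class SyntheticGroundTruth:
    """Everything planted by a simulation run, for recovery checks."""

    embedding_truth: EmbeddingSpace
    category_of_word: dict[str, str]
    true_weights: np.ndarray
    noise_sd: float
    true_word_rdm: DissimilarityMatrix
    master_seed: int
    region_labels: np.ndarray | None = None
    delay_gains: tuple[float, ...] = DEFAULT_DELAY_GAINS

    def __post_init__(self) -> None:
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        if self.true_weights.shape[0] != self.embedding_truth.n_dims:
            raise ValueError(
                "true_weights rows must match the embedding dimension"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def movie_schedule(
    n_train_clips: int = 12,
    n_test_clips: int = 2,
    clip_seconds: int = 610,
    dummy_seconds: int = 10,
    tr_seconds: int = 1,
) -> dict[str, int]:
    """Sample bookkeeping for the movie protocol.

    Each clip opens with a dummy lead-in that is discarded to skip the
    hemodynamic onset transient; training clips are shown once and test clips
    are repeated and averaged, so the test set contributes one usable series
    per clip. Defaults give 7200 training and 1200 test samples at TR = 1 s.
    """
    usable = (clip_seconds - dummy_seconds) // tr_seconds
    if usable <= 0:
        raise ValueError("clip shorter than its dummy lead-in")
    return {
        "samples_per_clip": usable,
        "n_train": n_train_clips * usable,
        "n_test": n_test_clips * usable,
    }


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def make_embedding_truth(
    n_words: int,
    n_dims: int,
    n_categories: int,
    within_category_corr: float,
    seed: int,
    words: Sequence[str] | None = None,
) -> tuple[EmbeddingSpace, dict[str, str]]:
    """Category-structured ground-truth embedding.

    Each word vector is ``sqrt(c) * centroid + sqrt(1 - c) * noise`` with the
    centroid shared within its category, so the expected correlation between
    same-category words is ``c = within_category_corr`` and between-category
    words 0 — analytic control over the planted similarity structure. With
    ``words=None`` labels are ``cat<i>_word<j>``; passing the 60-noun task
    vocabulary aligns the simulation with the behavioral word set.
    """
    if n_categories < 1 or n_words % n_categories != 0:
        raise ValueError("category partition impossible: n_words must divide evenly")
    if not 0 <= within_category_corr < 1:
        raise ValueError("within_category_corr must lie in [0, 1)")
    if n_dims < 2:
        raise ValueError("need n_dims >= 2")
    per_cat = n_words // n_categories
    if words is None:
        words = [
            f"cat{i}_word{j}" for i in range(n_categories) for j in range(per_cat)
        ]
        categories = [f"cat{i}" for i in range(n_categories)]
    else:
        words = list(words)
        if len(words) != n_words:
            raise ValueError(f"{len(words)} words supplied, expected {n_words}")
        categories = [f"cat{i}" for i in range(n_categories)]

    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_categories, n_dims))
    noise = rng.standard_normal((n_words, n_dims))
    cat_idx = np.repeat(np.arange(n_categories), per_cat)
    c = within_category_corr
    vectors = np.sqrt(c) * centroids[cat_idx] + np.sqrt(1 - c) * noise
    space = EmbeddingSpace(words=words, vectors=vectors, kind="trained",
                           instance_seed=int(seed))
    category_of_word = {w: categories[cat_idx[i]] for i, w in enumerate(words)}
    return space, category_of_word


def task_noun_embedding_truth(
    n_dims: int, within_category_corr: float, seed: int
) -> tuple[EmbeddingSpace, dict[str, str]]:
    """Embedding truth over the packaged 60-noun, 6-category vocabulary."""
    space, _ = make_embedding_truth(
        n_words=60, n_dims=n_dims, n_categories=6,
        within_category_corr=within_category_corr, seed=seed, words=TASK_NOUNS,
    )
    from .wordsets import NOUN_CATEGORY_OF

    return space, dict(NOUN_CATEGORY_OF)


# ---------------------------------------------------------------------------
# scene streams
# ---------------------------------------------------------------------------

def make_scene_stream(
    embedding: EmbeddingSpace,
    n_scenes: int,
    n_annotators: int = 2,
    words_per_description: int = 10,
    seed: int = 0,
    n_test: int = 0,
    topic_persistence: float = 0.9,
    topic_fidelity: float = 0.7,
    topic_pool_size: int = 10,
) -> tuple[list[SceneDescription], SceneFeatureSeries]:
    """Annotator token streams plus their exact scene-vector series.

    Scenes carry a latent topic — a random pool of ``topic_pool_size``
    vocabulary words standing in for "what is on screen" — evolving as a
    sticky Markov chain: with probability ``topic_persistence`` the pool
    carries over to the next second, so consecutive scene vectors correlate
    as movie scenes do. Each of ``n_annotators`` descriptions samples
    ``words_per_description`` tokens, drawn from the current pool with
    probability ``topic_fidelity`` and uniformly from the vocabulary
    otherwise. Topic pools are sampled uniformly, *not* along semantic
    categories: words that are similar in the embedding need not co-occur in
    scenes, just as on screen a sea is not usually accompanied by a mountain.
    The returned feature series is exactly ``scene_vector`` applied to the
    descriptions (cross-module consistency), with the last ``n_test`` scenes
    tagged test.
    """
    if embedding.n_words == 0:
        raise ValueError("empty vocabulary")
    if n_annotators < 1 or words_per_description < 1:
        raise ValueError("need at least one annotator and one word per description")
    if not 0 <= n_test <= n_scenes:
        raise ValueError("n_test must lie in [0, n_scenes]")
    rng = np.random.default_rng(seed)
    pool_size = min(int(topic_pool_size), embedding.n_words)

    def fresh_pool():
        return list(rng.choice(embedding.words, size=pool_size, replace=False))

    descriptions: list[SceneDescription] = []
    pool = fresh_pool()
    for s in range(n_scenes):
        if rng.random() > topic_persistence:
            pool = fresh_pool()
        for a in range(n_annotators):
            tokens = []
            for _ in range(words_per_description):
                if rng.random() < topic_fidelity:
                    tokens.append(pool[rng.integers(pool_size)])
                else:
                    tokens.append(embedding.words[rng.integers(embedding.n_words)])
            descriptions.append(
                SceneDescription(scene_id=s, annotator_id=f"annotator_{a}",
                                 tokens=tokens)
            )

    split = np.array(["train"] * (n_scenes - n_test) + ["test"] * n_test)
    series = _features.scene_feature_series(
        descriptions, embedding, n_scenes=n_scenes, split=split
    )
    return descriptions, series


# ---------------------------------------------------------------------------
# brains and responses
# ---------------------------------------------------------------------------

def make_brain_truth(
    embedding_dim: int,
    n_voxels: int,
    n_regions: int,
    tuned_fraction: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted K-by-N voxel tuning and contiguous region labels.

    Exactly ``round(tuned_fraction * n_voxels)`` voxels (chosen at random)
    receive dense Gaussian tuning with per-entry scale ``1/sqrt(K)``; the rest
    are pure-noise voxels with zero tuning. Region labels partition the voxels
    into ``n_regions`` contiguous, near-equal groups.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    if n_regions > n_voxels:
        raise ValueError("more regions than voxels")
    if not 0 <= tuned_fraction <= 1:
        raise ValueError("tuned_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_tuned = int(round(tuned_fraction * n_voxels))
    tuned = rng.choice(n_voxels, size=n_tuned, replace=False)
    weights = np.zeros((embedding_dim, n_voxels))
    weights[:, tuned] = rng.standard_normal((embedding_dim, n_tuned)) / np.sqrt(
        embedding_dim
    )
    sizes = np.full(n_regions, n_voxels // n_regions)
    sizes[: n_voxels % n_regions] += 1
    region_labels = np.repeat(
        [f"region_{i:03d}" for i in range(n_regions)], sizes
    ).astype(object)
    return weights, region_labels


def simulate_responses(
    scene_vectors: SceneFeatureSeries,
    true_weights: np.ndarray,
    delays=DEFAULT_DELAYS,
    gains=DEFAULT_DELAY_GAINS,
    noise_sd: float = 2.0,
    seed: int = 0,
    region_labels=None,
) -> ResponseSeries:
    """Forward model: delay-embedded scene vectors times delayed weights plus noise.

    The planted K-by-N weights are replicated across delay blocks with the
    fixed per-delay ``gains``; noise is i.i.d. Gaussian per time point per
    voxel (no temporal autocorrelation — a documented simplification). The
    train and test segments are embedded separately, as they come from
    separate scans.
    """
    true_weights = np.asarray(true_weights, dtype=float)
    if len(gains) != len(delays):
        raise ValueError("need one gain per delay")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if scene_vectors.n_features != true_weights.shape[0]:
        raise ValueError(
            f"scene vectors have {scene_vectors.n_features} features but "
            f"true_weights has {true_weights.shape[0]} rows"
        )
    w_delayed = np.vstack([g * true_weights for g in gains])
    rng = np.random.default_rng(seed)
    parts = []
    for tag in ("train", "test"):
        seg = scene_vectors.values[scene_vectors.split == tag]
        if seg.shape[0] == 0:
            continue
        signal = delay_embed(seg, delays) @ w_delayed
        parts.append(signal + noise_sd * rng.standard_normal(signal.shape))
    values = np.vstack(parts)
    return ResponseSeries(
        values=values, region_labels=region_labels, split=scene_vectors.split,
        tr_seconds=scene_vectors.tr_seconds,
    )


# ---------------------------------------------------------------------------
# simulated arrangement participant
# ---------------------------------------------------------------------------

def _classical_mds_2d(dissim: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) metric scaling to 2 dimensions."""
    n = dissim.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dissim**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:2]
    top = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(top)


def simulated_subject_place(
    true_rdm: DissimilarityMatrix,
    subset: Sequence[str],
    position_noise: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """A simulated participant's 2-D placement of a word subset.

    The subset's sub-RDM is embedded by classical 2-D metric scaling, rescaled
    to fit the arena (farthest word on the rim), randomly rotated, and
    jittered with isotropic Gaussian noise of standard deviation
    ``position_noise`` times the arena radius. Jittered points straying
    outside are pulled back to the rim. Deterministic under ``seed``.
    """
    subset = list(subset)
    if len(subset) < 3:
        raise ValueError("unarrangeable subset: need at least 3 words")
    if position_noise < 0:
        raise ValueError("position_noise must be >= 0")
    sub = subset_rdm(true_rdm, subset)
    coords = _classical_mds_2d(sub.values)
    coords -= coords.mean(axis=0)
    max_norm = np.linalg.norm(coords, axis=1).max()
    if max_norm > 0:
        coords *= ARENA_RADIUS / max_norm
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    coords = coords @ rot.T
    coords += position_noise * ARENA_RADIUS * rng.standard_normal(coords.shape)
    norms = np.linalg.norm(coords, axis=1)
    outside = norms > ARENA_RADIUS
    if outside.any():
        coords[outside] *= (ARENA_RADIUS / norms[outside])[:, None]
    return coords


def planar_word_rdm(
    n_words: int, seed: int = 0, labels: Sequence[str] | None = None
) -> DissimilarityMatrix:
    """Euclidean RDM of random planar points — exactly 2-D-embeddable truth.

    Useful for arrangement recovery experiments: a noiseless subject can
    reproduce it perfectly from a single full arrangement.
    """
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-1.0, 1.0, size=(n_words, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    if labels is None:
        labels = [f"word_{i:02d}" for i in range(n_words)]
    return DissimilarityMatrix(labels=list(labels), values=d, metric="behavioral")
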