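"""Core data containers shared across the pipeline.

Everything is a plain dataclass around numpy arrays with validation in
``__post_init__``: an :class:`EmbeddingSpace` (vocabulary plus word-by-dimension
matrix), a :class:`SceneFeatureSeries` (one feature vector per 1-s movie scene),
a :class:`ResponseSeries` (voxel time series with region labels), the fitted
:class:`EncodingModel` and its :class:`AccuracyProfile`, and the symmetric
:class:`DissimilarityMatrix` used by both model-derived and behavior-derived
representational analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

EMBEDDING_KINDS = ("trained", "untrained", "dimension_shuffled", "binary")
RDM_METRICS = ("correlation_distance", "behavioral")

#: Radius of the circular arrangement arena; all task geometry is expressed in
#: arena-diameter units, so the diameter is 1 and the radius 0.5.
ARENA_RADIUS = 0.5


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    return arr


def _check_unique(labels: Sequence[str], name: str) -> list[str]:
    labels = [str(w) for w in labels]
    seen: set[str] = set()
    for w in labels:
        if w in seen:
            raise ValueError(f"duplicate {name} label: {w!r}")
        seen.add(w)
    return labels


@dataclass
class EmbeddingSpace:
    """A vocabulary and its word-by-dimension real matrix.

    ``kind`` tags the provenance of the vectors: ``trained`` (statistically
    learned, or the planted synthetic truth), ``untrained`` (random vectors with
    word identity but no relational structure), ``dimension_shuffled`` (entries
    permuted within each word, the chance model) or ``binary`` (word-occurrence
    indicator features).
    """

    words: list[str]
    vectors: np.ndarray
    kind: str = "trained"
    instance_seed: int | None = None

    def __post_init__(self) -> None:
        self.words = _check_unique(self.words, "word")
        self.vectors = _as_float_matrix(self.vectors, "vectors")
        if self.vectors.shape[0] != len(self.words):
            raise ValueError(
                f"{len(self.words)} words but {self.vectors.shape[0]} vector rows"
            )
        if self.vectors.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors contain non-finite entries")
        if self.kind not in EMBEDDING_KINDS:
            raise ValueError(f"unknown embedding kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.vectors, (0.0, 1.0)).all():
            raise ValueError("binary embedding entries must be 0 or 1")
        self._index: dict[str, int] | None = None

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def n_dims(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {w: i for i, w in enumerate(self.words)}
        return self._index

    def subset(self, words: Sequence[str]) -> np.ndarray:
        """Rows for ``words`` in the given order; unknown word raises KeyError."""
        return self.vectors[[self.index[w] for w in words]]


@dataclass
class SceneDescription:
    """One annotator's token list for one 1-s movie scene."""

    scene_id: int
    annotator_id: str
    tokens: list[str]

    def __post_init__(self) -> None:
        self.scene_id = int(self.scene_id)
        if self.scene_id < 0:
            raise ValueError("scene_id must be >= 0")
        self.tokens = [str(t) for t in self.tokens]


def _check_split(split, n_rows: int) -> np.ndarray:
    if split is None:
        split = ["train"] * n_rows
    split = np.asarray(split, dtype=object)
    if split.shape != (n_rows,):
        raise ValueError("split must have one tag per row")
    bad = set(split) - {"train", "test"}
    if bad:
        raise ValueError(f"split tags must be 'train'/'test', got {sorted(bad)}")
    return split.astype("U5")


@dataclass
class SceneFeatureSeries:
    """Time-by-feature matrix of scene vectors at 1-s resolution."""

    values: np.ndarray
    split: np.ndarray | None = None
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "scene features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scene features contain non-finite entries")
        self.split = _check_split(self.split, self.values.shape[0])

    @property
    def n_scenes(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])

    def train_values(self) -> np.ndarray:
        return self.values[self.split == "train"]

    def test_values(self) -> np.ndarray:
        return self.values[self.split == "test"]


@dataclass
class ResponseSeries:
    """Time-by-voxel response matrix with per-voxel region labels."""

    values: np.ndarray
    region_labels: np.ndarray | None = None
    split: np.ndarray | None = None
    tr_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "responses")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("responses contain non-finite entries")
        n_voxels = self.values.shape[1]
        if self.region_labels is None:
            self.region_labels = np.array(["region_000"] * n_voxels, dtype=object)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.region_labels.shape != (n_voxels,):
            raise ValueError("region_labels must have one entry per voxel")
        self.split = _check_split(self.split, self.values.shape[0])

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[1])

    def train_values(self) -> np.ndarray:
        return self.values[self.split == "train"]

    def test_values(self) -> np.ndarray:
        return self.values[self.split == "test"]


@dataclass
class EncodingModel:
    """Fitted voxelwise linear model with hemodynamic delay structure.

    ``weights`` has one block of ``n_features`` rows per delay (blocks ordered as
    ``delays``), mapping delay-embedded scene features to voxel responses.
    """

    weights: np.ndarray
    delays: tuple[int, ...]
    lambda_: float
    feature_kind: str = "trained"
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = _as_float_matrix(self.weights, "weights")
        self.delays = tuple(int(d) for d in self.delays)
        if len(self.delays) == 0:
            raise ValueError("delays must be nonempty")
        if self.weights.shape[0] % len(self.delays) != 0:
            raise ValueError(
                f"weight rows {self.weights.shape[0]} not divisible by "
                f"{len(self.delays)} delays"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite entries")
        self.lambda_ = float(self.lambda_)
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    @property
    def n_features(self) -> int:
        return self.weights.shape[0] // len(self.delays)

    @property
    def n_voxels(self) -> int:
        return int(self.weights.shape[1])


@dataclass
class AccuracyProfile:
    """Per-voxel prediction accuracy (Pearson r) with FDR significance."""

    per_voxel_r: np.ndarray
    n_test: int
    p_values: np.ndarray
    significant_mask: np.ndarray
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.per_voxel_r = np.asarray(self.per_voxel_r, dtype=float).ravel()
        self.p_values = np.asarray(self.p_values, dtype=float).ravel()
        self.significant_mask = np.asarray(self.significant_mask, dtype=bool).ravel()
        n = self.per_voxel_r.shape[0]
        if self.p_values.shape[0] != n or self.significant_mask.shape[0] != n:
            raise ValueError("accuracy profile arrays must have equal length")
        if np.any(np.abs(self.per_voxel_r) > 1 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=object)
            if self.region_labels.shape != (n,):
                raise ValueError("region_labels must have one entry per voxel")
        self.n_test = int(self.n_test)

    @property
    def n_voxels(self) -> int:
        return int(self.per_voxel_r.shape[0])


@dataclass
class DissimilarityMatrix:
    """Symmetric word-by-word dissimilarity table.

    ``metric`` is ``correlation_distance`` (entries in [0, 2], one minus Pearson
    correlation of representations) or ``behavioral`` (nonnegative scale-free
    estimates from arrangement data; entries for never-co-arranged pairs may be
    NaN, meaning missing).
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "correlation_distance"

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, "word")
        self.values = _as_float_matrix(self.values, "dissimilarities")
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValueError(
                f"{p} labels but value matrix of shape {self.values.shape}"
            )
        if self.metric not in RDM_METRICS:
            raise ValueError(f"unknown RDM metric {self.metric!r}")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("RDM diagonal must be zero")
        finite = np.isfinite(self.values)
        if self.metric == "correlation_distance" and not finite.all():
            raise ValueError("correlation-distance RDM must be complete")
        if not np.array_equal(finite, finite.T):
            raise ValueError("missing entries must be symmetric")
        asym = np.nanmax(np.abs(self.values - self.values.T)) if p else 0.0
        if asym > 1e-8:
            raise ValueError(f"RDM asymmetric (max deviation {asym:.3g})")
        vals = self.values[finite]
        if vals.size and vals.min() < -1e-9:
            raise ValueError("dissimilarities must be nonnegative")
        if self.metric == "correlation_distance" and vals.size and vals.max() > 2 + 1e-9:
            raise ValueError("correlation distances must lie in [0, 2]")
        self._index: dict[str, int] | None = None

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def index(self) -> dict[str, int]:
        if self._index is None:
            self._index = {w: i for i, w in enumerate(self.labels)}
        return self._index

    def upper_triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries in row-major order (may contain NaN)."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.values[iu]


@dataclass
class ArrangementTrial:
    """One arrangement: a word subset placed in the unit-diameter arena."""

    trial_index: int
    words: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.trial_index = int(self.trial_index)
        self.words = _check_unique(self.words, "word")
        self.positions = _as_float_matrix(self.positions, "positions")
        if self.positions.shape != (len(self.words), 2):
            raise ValueError("positions must be an n_words-by-2 matrix")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")
        radii = np.linalg.norm(self.positions, axis=1)
        if np.any(radii > ARENA_RADIUS + 1e-9):
            raise ValueError("positions outside the unit-diameter arena")


@dataclass
class EvidenceState:
    """Running dissimilarity estimate with per-pair evidence in [0, 1]."""

    estimate: DissimilarityMatrix
    evidence: np.ndarray
    trial_scales: list[float]
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.evidence = _as_float_matrix(self.evidence, "evidence")
        p = self.estimate.n_items
        if self.evidence.shape != (p, p):
            raise ValueError("evidence shape must match the estimate")
        if not np.allclose(self.evidence, self.evidence.T, atol=1e-9):
            raise ValueError("evidence must be symmetric")
        if self.evidence.min() < -1e-12 or self.evidence.max() > 1 + 1e-12:
            raise ValueError("evidence must lie in [0, 1]")
        self.trial_scales = [float(s) for s in self.trial_scales]

    def min_evidence(self) -> float:
        """Smallest off-diagonal evidence value."""
        p = self.estimate.n_items
        iu = np.triu_indices(p, k=1)
        return float(self.evidence[iu].min()) if p > 1 else 1.0


#: A simulated (or wrapped human) participant: maps a word subset and a seed to
#: per-word 2-D positions inside the arena.
SubjectCallback = Callable[[Sequence[str], int], np.ndarray]
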