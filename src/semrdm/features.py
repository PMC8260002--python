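"""Semantic feature spaces and scene vectors.

Four kinds of word features drive the encoding models: trained embeddings
(read from word2vec text files or planted synthetically), untrained random
vectors (word identity without relational structure), dimension-shuffled
controls (each word's entries permuted independently — the chance model), and
binary word-occurrence labels. Scene descriptions are turned into scene vectors
by a two-level average: word vectors are averaged within each description, and
the per-description means are then averaged across descriptions of the scene.
This is *not* a pooled mean over all tokens — descriptions with more words do
not get more weight.
"""

from __future__ import annotations

import collections
from typing import Iterable, Sequence

import numpy as np

from .types import EmbeddingSpace, SceneDescription, SceneFeatureSeries

__all__ = [
    "read_embeddings",
    "write_embeddings",
    "scene_vector",
    "scene_feature_series",
    "binary_scene_features",
    "untrained_space",
    "shuffle_dimensions",
    "read_descriptions_tsv",
    "write_descriptions_tsv",
]


# ---------------------------------------------------------------------------
# word2vec text format I/O
# ---------------------------------------------------------------------------

def read_embeddings(path) -> EmbeddingSpace:
    """Read an embedding space in word2vec text format.

    The file may start with an optional ``"P K"`` header line; every other line
    is a word followed by K space-separated numbers. Vocabulary order is
    preserved, duplicate words are an error, and ragged rows are reported with
    their line number.
    """
    words: list[str] = []
    rows: list[list[float]] = []
    n_dims: int | None = None
    declared: tuple[int, int] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if line_no == 1 and len(parts) == 2:
                try:
                    declared = (int(parts[0]), int(parts[1]))
                    continue
                except ValueError:
                    pass  # not a header: fall through and parse as a row
            word, values = parts[0], parts[1:]
            if not values:
                raise ValueError(f"{path}: line {line_no} has no vector entries")
            if n_dims is None:
                n_dims = len(values)
            elif len(values) != n_dims:
                raise ValueError(
                    f"{path}: line {line_no} has {len(values)} entries, "
                    f"expected {n_dims}"
                )
            if word in set(words):
                raise ValueError(f"{path}: duplicate word {word!r} at line {line_no}")
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise ValueError(f"{path}: line {line_no}: {exc}") from None
            words.append(word)
    if not words:
        raise ValueError(f"{path}: no embedding rows found")
    if declared is not None and declared != (len(words), n_dims):
        raise ValueError(
            f"{path}: header declares {declared[0]}x{declared[1]} but file "
            f"contains {len(words)}x{n_dims}"
        )
    return EmbeddingSpace(words=words, vectors=np.array(rows), kind="trained")


def write_embeddings(space: EmbeddingSpace, path, header: bool = True) -> None:
    """Write ``space`` in word2vec text format (with a ``"P K"`` header)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{space.n_words} {space.n_dims}\n")
        for word, row in zip(space.words, space.vectors):
            fh.write(word + " " + " ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# scene vectors
# ---------------------------------------------------------------------------

def scene_vector(
    descriptions: Sequence[SceneDescription],
    embedding: EmbeddingSpace,
    allow_featureless: bool = False,
) -> np.ndarray:
    """Two-level average of word vectors for one scene.

    Word vectors are averaged within each description; the per-description
    means are then averaged (unweighted) across descriptions. Out-of-vocabulary
    tokens are dropped; a description that loses all its tokens contributes
    nothing. If no description retains a token, a "featureless scene" error is
    raised unless ``allow_featureless``, in which case the zero vector is
    returned.
    """
    if not descriptions:
        raise ValueError("featureless scene: no descriptions given")
    index = embedding.index
    means = []
    for desc in descriptions:
        rows = [embedding.vectors[index[t]] for t in desc.tokens if t in index]
        if rows:
            means.append(np.mean(rows, axis=0))
    if not means:
        if allow_featureless:
            return np.zeros(embedding.n_dims)
        raise ValueError(
            f"featureless scene {descriptions[0].scene_id}: no in-vocabulary token"
        )
    return np.mean(means, axis=0)


def _group_by_scene(
    descriptions: Iterable[SceneDescription],
) -> dict[int, list[SceneDescription]]:
    by_scene: dict[int, list[SceneDescription]] = collections.defaultdict(list)
    for desc in descriptions:
        by_scene[desc.scene_id].append(desc)
    return by_scene


def scene_feature_series(
    descriptions: Sequence[SceneDescription],
    embedding: EmbeddingSpace,
    n_scenes: int | None = None,
    split=None,
    allow_featureless: bool = False,
) -> SceneFeatureSeries:
    """Stack :func:`scene_vector` over all scenes into an S-by-K series.

    Scene ids must cover ``0 .. n_scenes-1``; ``n_scenes`` defaults to the
    largest scene id plus one.
    """
    by_scene = _group_by_scene(descriptions)
    if n_scenes is None:
        n_scenes = max(by_scene) + 1 if by_scene else 0
    values = np.zeros((n_scenes, embedding.n_dims))
    for s in range(n_scenes):
        if s not in by_scene:
            raise ValueError(f"scene {s} has no descriptions")
        values[s] = scene_vector(by_scene[s], embedding, allow_featureless)
    return SceneFeatureSeries(values=values, split=split)


def binary_scene_features(
    descriptions: Sequence[SceneDescription],
    top_n: int,
    n_scenes: int | None = None,
    split=None,
) -> tuple[list[str], SceneFeatureSeries]:
    """Binary word-occurrence features over the ``top_n`` most frequent words.

    Word frequency is counted over all token occurrences in all descriptions;
    frequency ties are broken lexicographically for deterministic builds.
    Feature (s, k) is 1 iff vocabulary word k appears in *any* description of
    scene s.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts = collections.Counter()
    for desc in descriptions:
        counts.update(desc.tokens)
    if top_n > len(counts):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(counts)} distinct words observed"
        )
    vocab = sorted(counts, key=lambda w: (-counts[w], w))[:top_n]
    vocab_index = {w: k for k, w in enumerate(vocab)}

    by_scene = _group_by_scene(descriptions)
    if n_scenes is None:
        n_scenes = max(by_scene) + 1 if by_scene else 0
    values = np.zeros((n_scenes, top_n))
    for s, descs in by_scene.items():
        for desc in descs:
            for tok in desc.tokens:
                k = vocab_index.get(tok)
                if k is not None:
                    values[s, k] = 1.0
    return vocab, SceneFeatureSeries(values=values, split=split)


# ---------------------------------------------------------------------------
# control feature spaces
# ---------------------------------------------------------------------------

def untrained_space(template: EmbeddingSpace, seed: int) -> EmbeddingSpace:
    """Random vectors with the template's vocabulary and dimensionality.

    Entries are i.i.d. standard normal, so words keep their identity but carry
    no relational structure. Evaluation conventionally averages five
    independent instances (seeds).
    """
    rng = np.random.default_rng(seed)
    vectors = rng.standard_normal((template.n_words, template.n_dims))
    return EmbeddingSpace(
        words=list(template.words), vectors=vectors, kind="untrained",
        instance_seed=int(seed),
    )


def shuffle_dimensions(space: EmbeddingSpace, seed: int) -> EmbeddingSpace:
    """Permute each word's entries independently across dimensions.

    Per-word entry multisets (hence norms) are preserved while the relational
    structure between words is destroyed — the chance model for encoding
    performance. Five independent instances are conventionally averaged.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.empty_like(space.vectors)
    for i in range(space.n_words):
        shuffled[i] = space.vectors[i, rng.permutation(space.n_dims)]
    return EmbeddingSpace(
        words=list(space.words), vectors=shuffled, kind="dimension_shuffled",
        instance_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# description I/O (TSV: scene_id, annotator_id, space-joined tokens)
# ---------------------------------------------------------------------------

def write_descriptions_tsv(descriptions: Sequence[SceneDescription], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("scene_id\tannotator_id\ttokens\n")
        for d in descriptions:
            fh.write(f"{d.scene_id}\t{d.annotator_id}\t{' '.join(d.tokens)}\n")


def read_descriptions_tsv(path) -> list[SceneDescription]:
    out: list[SceneDescription] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["scene_id", "annotator_id", "tokens"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {line_no} has {len(parts)} fields")
            out.append(
                SceneDescription(
                    scene_id=int(parts[0]),
                    annotator_id=parts[1],
                    tokens=parts[2].split(),
                )
            )
    return out
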