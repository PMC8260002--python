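import numpy as np
import pytest

from semrdm.types import DissimilarityMatrix, EmbeddingSpace, SceneDescription


@pytest.fixture
def toy_embedding() -> EmbeddingSpace:
    """Three words in 2-D, hand-pickable numbers."""
    return EmbeddingSpace(
        words=["a", "b", "c"],
        vectors=np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 3.0]]),
    )


@pytest.fixture
def random_embedding() -> EmbeddingSpace:
    rng = np.random.default_rng(7)
    return EmbeddingSpace(
        words=[f"w{i}" for i in range(30)],
        vectors=rng.standard_normal((30, 12)),
    )


@pytest.fixture
def two_descriptions() -> list[SceneDescription]:
    """One scene, two annotators: {a} and {b, c}."""
    return [
        SceneDescription(scene_id=0, annotator_id="a1", tokens=["a"]),
        SceneDescription(scene_id=0, annotator_id="a2", tokens=["b", "c"]),
    ]


def random_rdm(n: int, seed: int, metric: str = "behavioral") -> DissimilarityMatrix:
    """An unstructured RDM (correlation distances of random representations)."""
    rng = np.random.default_rng(seed)
    reps = rng.standard_normal((n, max(4, n // 2)))
    c = np.corrcoef(reps)
    vals = 1.0 - (c + c.T) / 2
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix(
        labels=[f"w{i}" for i in range(n)], values=np.clip(vals, 0, 2), metric=metric
    )
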