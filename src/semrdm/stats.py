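"""Rank correlations and permutation inference for dissimilarity matrices.

RDMs are compared by rank correlation (Spearman by default, Kendall available)
over their strictly-upper triangles. Significance comes from permutation nulls:
the item labels of one matrix are shuffled (rows and columns together, which
preserves symmetry) and the correlation recomputed, 10,000 times by default;
small item sets are enumerated exhaustively. Differences of correlations are
tested the same way with independent shuffles per pair. Multiple comparisons
use Benjamini–Hochberg FDR; paired region-level comparisons use the Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import DissimilarityMatrix

__all__ = [
    "PermutationResult",
    "rank_correlation",
    "rdm_correlation",
    "permutation_pvalue",
    "permutation_diff_pvalue",
    "fdr_bh",
    "wilcoxon_paired",
]


@dataclass
class PermutationResult:
    """Observed statistic and permutation p-value."""

    observed: float
    p_value: float
    n_perm: int
    scheme: str
    sided: str
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------

def rank_correlation(a, b, method: str = "spearman") -> float:
    """Spearman rho (average ranks for ties) or Kendall tau-b.

    Entries where either vector is NaN (missing pairs) are excluded pairwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 usable pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    if method == "spearman":
        return float(scipy.stats.spearmanr(a, b).statistic)
    if method == "kendall":
        return float(scipy.stats.kendalltau(a, b).statistic)
    raise ValueError("method must be 'spearman' or 'kendall'")


def _aligned_triangles(
    rdm_a: DissimilarityMatrix, rdm_b: DissimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDM labels must match (use subset_rdm to align)")
    return rdm_a.upper_triangle(), rdm_b.upper_triangle()


def rdm_correlation(
    rdm_a: DissimilarityMatrix, rdm_b: DissimilarityMatrix, method: str = "spearman"
) -> float:
    """Rank correlation between the strictly-upper triangles of two RDMs."""
    ta, tb = _aligned_triangles(rdm_a, rdm_b)
    return rank_correlation(ta, tb, method=method)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _null_triangle(values: np.ndarray, perm: np.ndarray, scheme: str, iu) -> np.ndarray:
    if scheme == "relabel":
        return values[np.ix_(perm, perm)][iu]
    if scheme == "rows_only":
        # Literal row shuffle: the matrix becomes asymmetric and the upper
        # triangle is taken from it as-is.
        return values[perm][iu]
    raise ValueError("scheme must be 'relabel' or 'rows_only'")


def _spearman_against_ranked(fixed_ranks: np.ndarray, x: np.ndarray) -> float:
    rx = scipy.stats.rankdata(x)
    rx -= rx.mean()
    return float(fixed_ranks @ rx / np.sqrt((fixed_ranks @ fixed_ranks) * (rx @ rx)))


def permutation_pvalue(
    rdm_fixed: DissimilarityMatrix,
    rdm_permuted: DissimilarityMatrix,
    n_perm: int = 10_000,
    scheme: str = "relabel",
    sided: str = "one",
    seed: int = 0,
    method: str = "spearman",
) -> PermutationResult:
    """Permutation p-value for the correlation between two RDMs.

    The null shuffles the item labels of ``rdm_permuted`` (``relabel``: rows
    and columns together; ``rows_only``: literal row shuffle). When P! <= the
    requested number of permutations the null is enumerated exhaustively and
    the p-value is the exact fraction of relabelings (identity included)
    reaching the observed statistic; otherwise the Monte-Carlo add-one
    estimator is used, so p is never exactly zero.
    """
    ta, tb = _aligned_triangles(rdm_fixed, rdm_permuted)
    if np.isfinite(ta).sum() < 3:
        raise ValueError("need at least 3 items")
    observed = rank_correlation(ta, tb, method=method)
    P = rdm_permuted.n_items
    iu = np.triu_indices(P, k=1)
    values = rdm_permuted.values
    missing = not (np.isfinite(ta).all() and np.isfinite(values).all())

    def stat(null_tri: np.ndarray) -> float:
        if missing or method != "spearman":
            return rank_correlation(ta, null_tri, method=method)
        return _spearman_against_ranked(fixed_ranks, null_tri)

    if not missing and method == "spearman":
        fixed_ranks = scipy.stats.rankdata(ta)
        fixed_ranks -= fixed_ranks.mean()

    exhaustive = math.factorial(P) <= n_perm
    if exhaustive:
        nulls = np.array(
            [
                stat(_null_triangle(values, np.array(perm), scheme, iu))
                for perm in itertools.permutations(range(P))
            ]
        )
        n_total = nulls.size
        if sided == "one":
            p = float((nulls >= observed - 1e-12).sum()) / n_total
        else:
            p = float((np.abs(nulls) >= abs(observed) - 1e-12).sum()) / n_total
        return PermutationResult(observed, p, n_total, scheme, sided, seed, True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(P)
        null = stat(_null_triangle(values, perm, scheme, iu))
        if sided == "one":
            count += null >= observed - 1e-12
        else:
            count += abs(null) >= abs(observed) - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(observed, float(p), n_perm, scheme, sided, seed, False)


def permutation_diff_pvalue(
    pair_1: tuple[DissimilarityMatrix, DissimilarityMatrix],
    pair_2: tuple[DissimilarityMatrix, DissimilarityMatrix],
    n_perm: int = 10_000,
    scheme: str = "relabel",
    sided: str = "two",
    seed: int = 0,
    method: str = "spearman",
) -> PermutationResult:
    """Permutation test for a difference of RDM correlations.

    Each pair is (fixed, permuted); the null distribution of the correlation
    difference comes from shuffling the permuted member of each pair
    independently in every repetition. Two-sided by default.
    """
    obs = rdm_correlation(*pair_1, method=method) - rdm_correlation(
        *pair_2, method=method
    )
    rng = np.random.default_rng(seed)

    prepared = []
    for fixed, permuted in (pair_1, pair_2):
        ta, _ = _aligned_triangles(fixed, permuted)
        P = permuted.n_items
        prepared.append((ta, permuted.values, P, np.triu_indices(P, k=1)))

    count = 0
    for _ in range(n_perm):
        null_rhos = []
        for ta, values, P, iu in prepared:
            perm = rng.permutation(P)
            null_rhos.append(
                rank_correlation(ta, _null_triangle(values, perm, scheme, iu), method)
            )
        delta = null_rhos[0] - null_rhos[1]
        if sided == "two":
            count += abs(delta) >= abs(obs) - 1e-12
        else:
            count += delta >= obs - 1e-12
    p = (1 + count) / (1 + n_perm)
    return PermutationResult(float(obs), float(p), n_perm, scheme, sided, seed, False)


# ---------------------------------------------------------------------------
# multiple comparisons & paired tests
# ---------------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def wilcoxon_paired(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; the test is exact for up to 25 informative
    pairs and uses the normal approximation beyond that.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("degenerate comparison: all differences are zero")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    method = "exact" if d.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)
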