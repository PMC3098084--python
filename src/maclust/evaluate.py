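"""Partition scoring: Rand, adjusted Rand, the ten-to-two optimal merge and
its simulated null distribution.

The evaluation emulates visual dendrogram inspection: a method predicts ten
clusters, which are then exhaustively joined into two groups so as to
maximize the adjusted Rand index against the known two classes.  Because the
merge optimizes the score, its chance expectation is positive; the null
distribution is estimated by scoring random ten-cluster partitions the same
way.

All pair counts come from the s × t contingency table (O(s·t)), never from
explicit O(n²) pair enumeration; the adjusted Rand index is the standard
Hubert–Arabie permutation-model form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "PairCounts",
    "MergedScore",
    "NullSummary",
    "contingency",
    "pair_counts",
    "rand_index",
    "adjusted_rand",
    "optimal_merge",
    "null_distribution",
]


class PairCounts(NamedTuple):
    a: int  # together in both partitions
    b: int  # apart in both
    c: int  # together in P, apart in Q
    d: int  # apart in P, together in Q


@dataclass
class MergedScore:
    """Best bipartition of the predicted clusters and its adjusted Rand."""

    merged_labels: np.ndarray  # 1/2 per sample
    arand: float
    group1_clusters: tuple  # predicted cluster labels merged into group 1


@dataclass
class NullSummary:
    samples: np.ndarray
    median: float
    q95: float


def contingency(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """s × t cross-tabulation of two label vectors over the same objects."""
    p = np.asarray(p)
    q = np.asarray(q)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("partitions must be 1-D and cover the same objects")
    _, pi = np.unique(p, return_inverse=True)
    _, qi = np.unique(q, return_inverse=True)
    table = np.zeros((pi.max() + 1, qi.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, qi), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_counts(p: np.ndarray, q: np.ndarray) -> PairCounts:
    """The four pair-agreement counts (a, b, c, d) between two partitions."""
    table = contingency(p, q)
    n = int(table.sum())
    if n < 2:
        raise ValueError("pair_counts: need >= 2 objects")
    total = n * (n - 1) // 2
    a = int(_comb2(table).sum())
    c = int(_comb2(table.sum(axis=1)).sum()) - a
    d = int(_comb2(table.sum(axis=0)).sum()) - a
    return PairCounts(a, total - a - c - d, c, d)


def rand_index(p: np.ndarray, q: np.ndarray) -> float:
    """Fraction of object pairs on which the two partitions agree."""
    pc = pair_counts(p, q)
    return (pc.a + pc.b) / (pc.a + pc.b + pc.c + pc.d)


def _ari_from_parts(sum_comb: float, sum_rows: float, sum_cols: float,
                    total: float) -> float:
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    if denom == 0:
        # both all-singletons or both one group: identical -> 1, else 0
        return 1.0 if sum_comb == max_index else 0.0
    return (sum_comb - expected) / denom


def adjusted_rand(p: np.ndarray, q: np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index; 1 iff identical up to labels.

    Degenerate denominators (both partitions all-singletons or both a single
    group) are defined as 1 when the partitions are equal and 0 otherwise.
    """
    table = contingency(p, q)
    n = int(table.sum())
    if n < 2:
        raise ValueError("adjusted_rand: need >= 2 objects")
    return _ari_from_parts(
        float(_comb2(table).sum()),
        float(_comb2(table.sum(axis=1)).sum()),
        float(_comb2(table.sum(axis=0)).sum()),
        float(n * (n - 1) // 2),
    )


def _bipartition_masks(c: int) -> np.ndarray:
    """All 2^(c-1) − 1 bipartitions of c items into two non-empty groups.

    Row r is the boolean membership of group 1; item 0 is always in group 1,
    so each bipartition appears exactly once.  Rows are ordered so that the
    first maximal score corresponds to the lexicographically smallest
    group-1 label set.
    """
    subsets = []
    for size in range(0, c):
        for extra in combinations(range(1, c), size):
            mask = np.zeros(c, dtype=bool)
            mask[0] = True
            mask[list(extra)] = True
            subsets.append(mask)
    subsets = subsets[:-1]  # drop the all-in-group-1 row (empty group 2)
    order = sorted(range(len(subsets)),
                   key=lambda i: tuple(np.where(subsets[i])[0]))
    return np.array([subsets[i] for i in order])


def optimal_merge(
    predicted: np.ndarray,
    truth: np.ndarray,
    target: int = 2,
) -> MergedScore:
    """Join predicted clusters into two groups maximizing adjusted Rand.

    Exhaustively scores all 2^(c−1) − 1 bipartitions of the c predicted
    cluster labels (c >= 2 required); ties go to the lexicographically
    smallest group-1 label set.
    """
    if target != 2:
        raise NotImplementedError("only the two-group merge is defined")
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    table = contingency(predicted, truth)  # c × t
    c = table.shape[0]
    if c < 2:
        raise ValueError("optimal_merge: predicted partition has < 2 clusters")
    n = int(table.sum())
    total = float(n * (n - 1) // 2)
    sum_cols = float(_comb2(table.sum(axis=0)).sum())

    masks = _bipartition_masks(c)  # n_bip × c
    g1 = masks.astype(np.int64) @ table  # n_bip × t
    g2 = table.sum(axis=0)[None, :] - g1
    sum_comb = _comb2(g1).sum(axis=1) + _comb2(g2).sum(axis=1)
    r1 = g1.sum(axis=1)
    sum_rows = _comb2(r1) + _comb2(n - r1)

    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    denom = max_index - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        ari = np.where(denom == 0,
                       np.where(sum_comb == max_index, 1.0, 0.0),
                       (sum_comb - expected) / denom)

    best_val = ari.max()
    best_i = int(np.argmax(ari == best_val))  # first == smallest label set
    cluster_labels = np.unique(predicted)
    group1 = cluster_labels[masks[best_i]]
    merged = np.where(np.isin(predicted, group1), 1, 2)
    return MergedScore(merged_labels=merged, arand=float(best_val),
                       group1_clusters=tuple(group1.tolist()))


def null_distribution(
    truth: np.ndarray,
    n_clusters: int = 10,
    reps: int = 1000,
    seed: Optional[int] = None,
) -> NullSummary:
    """Merged-aRand null: random uniform ten-cluster partitions vs truth.

    Each replicate assigns every sample independently and uniformly to one
    of ``n_clusters`` labels (empty labels allowed, leaving c < n_clusters
    for the merge), applies :func:`optimal_merge` and records the score.
    """
    if reps < 1:
        raise ValueError("null_distribution: reps must be >= 1")
    truth = np.asarray(truth)
    rng = np.random.default_rng(seed)
    n = len(truth)
    out = np.empty(reps)
    for r in range(reps):
        labels = rng.integers(1, n_clusters + 1, size=n)
        if len(np.unique(labels)) < 2:  # resample the measure-zero degenerate draw
            labels[0] = 1 if labels[0] != 1 else 2
        out[r] = optimal_merge(labels, truth).arand
    return NullSummary(samples=out, median=float(np.median(out)),
                       q95=float(np.quantile(out, 0.95)))
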