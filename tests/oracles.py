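"""Independent brute-force oracles used to pin expected values in the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_knn(points: np.ndarray, k: int) -> np.ndarray:
    """O(n^2) kNN adjacency; ties broken by smallest sample index."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    adj = np.zeros((n, n))
    for i in range(n):
        ranked = sorted(
            (float(np.linalg.norm(points[i] - points[j])), j)
            for j in range(n)
            if j != i
        )
        for _, j in ranked[:k]:
            adj[i, j] = 1
    return adj


def shared_neighbor_counts(adj: np.ndarray) -> np.ndarray:
    """|N(i) & N(j)| by explicit set intersection of out-neighbor sets."""
    n = adj.shape[0]
    nbrs = [set(np.flatnonzero(adj[i])) for i in range(n)]
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            counts[i, j] = len(nbrs[i] & nbrs[j])
    return counts


def direct_mi(counts: np.ndarray) -> float:
    """MI in nats by literal summation over the contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    a = counts.sum(axis=1)
    b = counts.sum(axis=0)
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            if counts[i, j] > 0:
                total += counts[i, j] / n * np.log(n * counts[i, j] / (a[i] * b[j]))
    return total


def _mi_over_arrangements(a, b) -> np.ndarray:
    """MI of x (margins a) against every distinct arrangement of the b-multiset.

    Distinct arrangements of the label multiset are equiprobable under a
    uniformly random permutation, so their MI values sample the permutation
    null exactly.
    """
    a = list(a)
    b = list(b)
    n = sum(a)
    x = np.repeat(np.arange(len(a)), a)
    y0 = np.repeat(np.arange(len(b)), b)
    arrangements = np.array(sorted(set(permutations(y0.tolist()))), dtype=np.int64)
    m = arrangements.shape[0]
    r, c = len(a), len(b)
    codes = x[None, :] * c + arrangements + np.arange(m)[:, None] * (r * c)
    tables = np.bincount(codes.ravel(), minlength=m * r * c).reshape(m, r * c)
    outer = np.outer(a, b).ravel()[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tables > 0, tables / n * np.log(n * tables / outer), 0.0)
    return terms.sum(axis=1)


def exhaustive_expected_mi(a, b) -> float:
    """Mean MI over all label permutations with margins a and b."""
    return float(_mi_over_arrangements(a, b).mean())


def exhaustive_mi_variance(a, b) -> float:
    """Population variance of MI over all label permutations."""
    return float(_mi_over_arrangements(a, b).var())


def set_partitions(items):
    """All partitions of a sequence into non-empty unordered blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        yield [[first]] + smaller


def integer_partitions(n: int):
    """All partitions of the integer n as non-increasing tuples."""
    if n == 0:
        yield ()
        return
    for head in range(n, 0, -1):
        for tail in integer_partitions(n - head):
            if not tail or head >= tail[0]:
                yield (head,) + tail
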