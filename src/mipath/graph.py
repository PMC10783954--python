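"""Per-pathway neighbor graphs: directed kNN plus shared-nearest-neighbor weights.

Each sample points to its k closest other samples under Euclidean distance in
the pathway subspace.  Edge (i, j) is then weighted by the fraction of i's
neighbors also found among j's neighbors, computed through the adjacency
identity B = A @ A.T: B_ij counts two-step paths i -> * <- j, i.e. shared
out-neighbors, and dividing by k maps it to [0, 1].  The weighted graph keeps
the kNN topology exactly: weights exist only on kNN edges, and zero-overlap
edges are retained with weight 0 so every node keeps out-degree k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
from scipy.spatial.distance import cdist

# exact brute-force search below this many samples; NN-descent above
EXACT_MAX_N = 2000

__all__ = ["NeighborGraph", "build_knn", "snn_weights", "write_edges", "EXACT_MAX_N"]


@dataclass
class NeighborGraph:
    """Directed kNN graph over samples with SNN similarities on its edges."""

    n_samples: int
    k: int
    adjacency: sparse.csr_matrix  # 0/1, exactly k out-edges per node, no self-loops
    weights: sparse.csr_matrix  # SNN similarity in [0, 1], same sparsity as adjacency

    def __post_init__(self) -> None:
        out_deg = np.diff(self.adjacency.indptr)
        if not np.all(out_deg == self.k):
            raise ValueError("adjacency must have out-degree exactly k at every node")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must not contain self-loops")


def build_knn(
    points: np.ndarray,
    k: int,
    mode: str = "auto",
    seed: int = 0,
) -> sparse.csr_matrix:
    """Directed k-nearest-neighbor adjacency under Euclidean distance.

    ``mode='exact'`` ranks all pairwise distances with a stable sort, so
    distance ties at the k-th neighbor break toward the smallest sample
    index and the result is deterministic.  ``mode='approximate'`` uses
    NN-descent (seeded, reproducible); ``'auto'`` switches to it above
    ``EXACT_MAX_N`` samples.  A point is never its own neighbor.
    """
    points = np.asarray(points, dtype=float)
    n, p = points.shape
    if p < 1:
        raise ValueError("points must have at least one feature")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples, got k={k}, n={n}")
    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "approximate"

    if mode == "exact":
        dist = cdist(points, points)
        np.fill_diagonal(dist, np.inf)
        # stable argsort: equal distances resolve to the smaller index
        nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
    elif mode == "approximate":
        from pynndescent import NNDescent

        index = NNDescent(
            points, n_neighbors=min(n - 1, k + 1), metric="euclidean", random_state=seed
        )
        ind, _ = index.neighbor_graph
        # drop self-hits, keep k neighbors per node
        nbrs = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            row = ind[i][ind[i] != i][:k]
            if len(row) < k:  # rare NN-descent shortfall: fill from exact ranking
                d = np.linalg.norm(points - points[i], axis=1)
                d[i] = np.inf
                order = np.argsort(d, kind="stable")
                extra = [j for j in order if j not in set(row)]
                row = np.concatenate([row, extra[: k - len(row)]])
            nbrs[i] = row
    else:
        raise ValueError(f"unknown kNN mode {mode!r}")

    rows = np.repeat(np.arange(n), k)
    adj = sparse.csr_matrix(
        (np.ones(n * k), (rows, nbrs.ravel())), shape=(n, n)
    )
    return adj


def snn_weights(adjacency: sparse.csr_matrix, k: int) -> NeighborGraph:
    """Weight each kNN edge by shared-neighbor overlap via B = A @ A.T.

    The weight on edge (i, j) is ``|N(i) & N(j)| / k`` with N the
    out-neighbor set.  Weights are attached only to edges of the kNN graph;
    edges with zero overlap keep an explicit zero weight.
    """
    adjacency = sparse.csr_matrix(adjacency)
    n = adjacency.shape[0]
    shared = adjacency @ adjacency.T  # B_ij = |N(i) & N(j)|
    rows, cols = adjacency.nonzero()
    overlap = np.asarray(shared[rows, cols]).ravel()
    weights = sparse.csr_matrix((overlap / k, (rows, cols)), shape=(n, n))
    return NeighborGraph(n_samples=n, k=k, adjacency=adjacency, weights=weights)


def build_graph(points: np.ndarray, k: int, mode: str = "auto", seed: int = 0) -> NeighborGraph:
    """Convenience: kNN construction followed by SNN weighting."""
    return snn_weights(build_knn(points, k, mode=mode, seed=seed), k)


def write_edges(graph: NeighborGraph, path, sample_ids=None) -> None:
    """Debug dump of the weighted graph as a (src, dst, weight) TSV."""
    ids = sample_ids or [str(i) for i in range(graph.n_samples)]
    rows, cols = graph.adjacency.nonzero()
    w = np.asarray(graph.weights[rows, cols]).ravel()
    with open(path, "w") as fh:
        fh.write("src\tdst\tweight\n")
        for r, c, x in zip(rows, cols, w):
            fh.write(f"{ids[r]}\t{ids[c]}\t{x:.6g}\n")
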