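"""The k-feature sample graph (k-FSG).

Samples become nodes; an undirected edge joins samples i and j whenever
either is among the other's K nearest neighbors, with Euclidean distance
measured over a chosen feature subset (OR-symmetrized K-NN graph). The
adjacency is binary with zero diagonal.

Neighborhood conventions
------------------------
K-NN graphs on discretized or low-resolution data are dominated by distance
ties, and published results built with different KNN searchers differ only
in how those ties are resolved. Two conventions are exposed:

``ties="expand"`` (default)
    The neighborhood of i is every sample whose distance is <= the K-th
    smallest distance from i. Needs no arbitrary tie-break and is
    equivariant under sample reordering even on tie-heavy data; neighborhoods
    may exceed K where ties occur.

``ties="strict"``
    Exactly K neighbors per sample; ties broken by ascending sample index.

``count_self=True`` additionally makes the sample itself occupy one of its
K neighbor slots, reproducing graphs built with KNN searchers that return
the query point as its own first neighbor (so K=2 yields one true neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset


class GraphError(ValueError):
    """Raised for invalid graph-construction parameters."""


@dataclass
class SampleGraph:
    """Binary symmetric adjacency over samples in a feature subspace."""

    adjacency: np.ndarray
    K: int
    feature_subset: tuple[int, ...]
    ties: str = "expand"
    count_self: bool = False

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.int8)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise GraphError("adjacency must be square")
        if (A != A.T).any():
            raise GraphError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise GraphError("adjacency diagonal must be zero")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (i, j) pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def to_edge_list_file(self, path: str | Path) -> None:
        """Write tab-separated 0-based node pairs, one edge per line."""
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in self.edge_list():
                fh.write(f"{i}\t{j}\n")


def pairwise_sq_distances(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance matrix, accumulated feature by feature.

    Summing per-feature squared differences in column order keeps the result
    bit-identical between a one-shot call and the incremental accumulation
    used by the greedy selector.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    D = np.zeros((m, m))
    for j in range(X.shape[1]):
        diff = X[:, j, None] - X[None, :, j]
        D += diff * diff
    return D


def knn_adjacency(
    sq_dist: np.ndarray,
    K: int,
    ties: str = "expand",
    count_self: bool = False,
) -> np.ndarray:
    """OR-symmetrized binary K-NN adjacency from a squared-distance matrix."""
    m = sq_dist.shape[0]
    if ties not in ("expand", "strict"):
        raise GraphError(f"unknown tie rule: {ties!r}")
    if K <= 0:
        raise GraphError("K must be positive")
    if K >= m:
        raise GraphError(f"K={K} must be < number of samples m={m}")
    k_eff = K - 1 if count_self else K
    A = np.zeros((m, m), dtype=np.int8)
    if k_eff == 0:
        return A  # self fills the only slot; edgeless graph
    D = sq_dist.copy().astype(float)
    np.fill_diagonal(D, np.inf)
    if ties == "strict":
        # stable argsort: among tied distances the lower sample index wins
        order = np.argsort(D, axis=1, kind="stable")[:, :k_eff]
        rows = np.repeat(np.arange(m), k_eff)
        A[rows, order.ravel()] = 1
    else:
        kth = np.partition(D, k_eff - 1, axis=1)[:, k_eff - 1]
        A[D <= kth[:, None]] = 1
    return np.maximum(A, A.T)


def build_ksg(
    ds: LabeledDataset,
    feature_subset: Sequence[int],
    K: int,
    ties: str = "expand",
    count_self: bool = False,
) -> SampleGraph:
    """Build the sample graph over ``ds`` restricted to ``feature_subset``.

    Parameters
    ----------
    ds : LabeledDataset
    feature_subset : sequence of int
        0-based column indices; must be non-empty and valid.
    K : int
        Neighbor count, ``1 <= K <= m-1``.
    ties, count_self
        Neighborhood convention, see module docstring.
    """
    subset = tuple(int(j) for j in feature_subset)
    if len(subset) == 0:
        raise GraphError("feature subset must be non-empty")
    n = ds.n_features
    if any(j < 0 or j >= n for j in subset):
        raise GraphError(f"feature index out of range 0..{n - 1}: {subset}")
    sq = pairwise_sq_distances(ds.values[:, subset])
    A = knn_adjacency(sq, K, ties=ties, count_self=count_self)
    return SampleGraph(
        adjacency=A, K=K, feature_subset=subset, ties=ties, count_self=count_self
    )
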