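"""Newman-Girvan community modularity Q of a sample graph.

Both printed forms of Q are implemented and must agree:

* pairwise form, summing over all ordered node pairs::

      Q = (1/2e) * sum_ij [ A_ij - d_i d_j / (2e) ] * delta(c_i, c_j)

* community form, summing over communities::

      Q = sum_c [ l_c / e - (d_c / 2e)^2 ]

where ``e`` counts each undirected edge once, ``d_i`` is the node degree,
``l_c`` the number of edges inside community c and ``d_c`` the degree sum of
community c. For feature scoring the partition is always the class-label
partition (communities = classes): a high Q means same-class samples are
densely interconnected and classes sparsely connected in the chosen feature
subspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset
from .graph import SampleGraph


class ModularityUndefinedError(ValueError):
    """Raised when Q is requested for an edgeless graph (division by e)."""


@dataclass
class ClassPartition:
    """Node-to-community map; codes are 0..n_communities-1, all occupied."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or len(self.codes) == 0:
            raise ValueError("partition codes must be a non-empty 1-D array")
        present = np.unique(self.codes)
        if present[0] != 0 or present[-1] != len(present) - 1:
            raise ValueError("community codes must be exactly 0..n_c-1")

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "ClassPartition":
        """Partition with communities = classes, re-coding if needed."""
        labels = np.asarray(labels)
        _, codes = np.unique(labels, return_inverse=True)
        return cls(codes=codes)

    @classmethod
    def from_dataset(cls, ds: LabeledDataset) -> "ClassPartition":
        return cls(codes=ds.labels.copy())

    @property
    def n_communities(self) -> int:
        return int(self.codes.max()) + 1


@dataclass
class ModularityReport:
    """Q with its per-community decomposition."""

    Q: float
    within_edges: np.ndarray  # l_c per community
    degree_sums: np.ndarray  # d_c per community
    edge_count: int  # e

    def __post_init__(self) -> None:
        self.within_edges = np.asarray(self.within_edges, dtype=np.int64)
        self.degree_sums = np.asarray(self.degree_sums, dtype=np.int64)
        if self.within_edges.sum() > self.edge_count:
            raise ValueError("sum of within-community edges exceeds e")
        if self.degree_sums.sum() != 2 * self.edge_count:
            raise ValueError("community degree sums must add to 2e")
        if not -1.0 - 1e-12 <= self.Q <= 1.0 + 1e-12:
            raise ValueError("Q outside [-1, 1]")

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "within_edges": self.within_edges.tolist(),
            "degree_sums": self.degree_sums.tolist(),
            "edge_count": self.edge_count,
        }


def _check(g: SampleGraph, p: ClassPartition) -> None:
    if len(p.codes) != g.n_nodes:
        raise ValueError("partition length must equal node count")
    if g.edge_count == 0:
        raise ModularityUndefinedError("modularity undefined for an edgeless graph")


def modularity_pairwise(g: SampleGraph, p: ClassPartition) -> float:
    """Q via the double sum over all ordered node pairs (including i=j;
    the adjacency diagonal is zero by construction)."""
    _check(g, p)
    A = g.adjacency.astype(float)
    d = g.degrees.astype(float)
    two_e = float(2 * g.edge_count)
    delta = p.codes[:, None] == p.codes[None, :]
    B = A - np.outer(d, d) / two_e
    return float(B[delta].sum() / two_e)


def modularity_community(g: SampleGraph, p: ClassPartition) -> ModularityReport:
    """Q via the per-community sum, with the l_c / d_c decomposition."""
    _check(g, p)
    e = g.edge_count
    degrees = g.degrees
    n_c = p.n_communities
    l_c = np.zeros(n_c, dtype=np.int64)
    d_c = np.zeros(n_c, dtype=np.int64)
    for c in range(n_c):
        members = p.codes == c
        l_c[c] = g.adjacency[np.ix_(members, members)].sum() // 2
        d_c[c] = degrees[members].sum()
    Q = float((l_c / e - (d_c / (2.0 * e)) ** 2).sum())
    return ModularityReport(Q=Q, within_edges=l_c, degree_sums=d_c, edge_count=e)
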