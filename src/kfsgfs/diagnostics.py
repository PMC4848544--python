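"""Cluster-geometry diagnostics linking graph modularity to class structure.

Two quantities connect a high-modularity feature subspace to small
within-class and large between-class distances:

* **ENC** — the expected number of samples correctly classified under
  stochastic (softmax) nearest-neighbor selection, as in neighborhood
  components analysis: sample i picks neighbor j with probability
  proportional to ``exp(-||x_i - x_j||^2)`` and is "correct" when the
  neighbor shares its class. ENIC = m - ENC is the expected number
  incorrectly classified.
* **J** — the k-means objective, the total squared Euclidean distance of
  each point to its assigned center (evaluation only, no Lloyd iterations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset
from .graph import pairwise_sq_distances


@dataclass
class NCAMatrix:
    """Softmax neighbor probabilities with per-sample correctness."""

    P: np.ndarray  # m x m row-stochastic, zero diagonal
    P_correct: np.ndarray  # P_i = sum over same-class j != i of P_ij
    enc: float
    enic: float

    def __post_init__(self) -> None:
        m = self.P.shape[0]
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each row of P must sum to 1")
        if np.diagonal(self.P).any():
            raise ValueError("P must have a zero diagonal")
        if ((self.P_correct < -1e-12) | (self.P_correct > 1 + 1e-12)).any():
            raise ValueError("per-sample probabilities must lie in [0, 1]")
        if abs((self.enc + self.enic) - m) > 1e-9:
            raise ValueError("ENC + ENIC must equal the sample count")


@dataclass
class KMeansObjective:
    """Evaluated k-means cost for a given assignment."""

    J: float
    centers: np.ndarray
    assignment: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("J must be non-negative")


def expected_correct_count(
    ds: LabeledDataset,
    subset: Sequence[int],
    squared: bool = True,
) -> NCAMatrix:
    """Softmax neighbor matrix and ENC over the columns in ``subset``.

    ``P_ij = exp(-d_ij) / sum_{j' != i} exp(-d_ij')`` with ``d`` the squared
    (default) or plain Euclidean distance restricted to ``subset``. Rows are
    max-shifted before exponentiation so microarray-scale distances do not
    underflow. ENC is the sum over samples of the probability that the
    stochastically chosen neighbor has the same class; ENIC = m - ENC.
    """
    subset = [int(j) for j in subset]
    if not subset:
        raise ValueError("subset must be non-empty")
    m = ds.n_samples
    if m < 2:
        raise ValueError("at least 2 samples are required")
    d = pairwise_sq_distances(ds.values[:, subset])
    if not squared:
        d = np.sqrt(d)
    logits = -d
    np.fill_diagonal(logits, -np.inf)
    shift = logits.max(axis=1, keepdims=True)
    w = np.exp(logits - shift)
    np.fill_diagonal(w, 0.0)
    P = w / w.sum(axis=1, keepdims=True)
    same = ds.labels[:, None] == ds.labels[None, :]
    P_i = (P * same).sum(axis=1)
    enc = float(P_i.sum())
    return NCAMatrix(P=P, P_correct=P_i, enc=enc, enic=float(m) - enc)


def kmeans_objective(
    points: np.ndarray,
    centers: np.ndarray,
    assignment: Sequence[int],
) -> KMeansObjective:
    """Total squared Euclidean distance of each point to its assigned center.

    Evaluation only: no center updates, no iteration. ``J = 0`` exactly when
    every point coincides with its assigned center.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    assignment = np.asarray(assignment, dtype=np.int64)
    if points.shape[0] != len(assignment):
        raise ValueError("one assignment per point is required")
    if points.shape[1] != centers.shape[1]:
        raise ValueError("points and centers must share a dimension")
    if ((assignment < 0) | (assignment >= centers.shape[0])).any():
        raise ValueError("assignment index out of range for centers")
    resid = points - centers[assignment]
    J = float((resid * resid).sum())
    return KMeansObjective(
        J=J, centers=centers, assignment=assignment, n_clusters=centers.shape[0]
    )
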