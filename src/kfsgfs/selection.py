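"""Greedy forward feature selection by sample-graph modularity (k-FSGFS).

At each step the selector adds the feature f that maximizes the community
modularity Q of the K-NN sample graph built in the subspace S + {f}, with
the class labels as the partition, until |S| = P features are selected.
Pure forward search: no removals, no backtracking.

Candidates are scanned in ascending column index and the argmax keeps the
first (lowest-index) maximizer, so traces are deterministic. Squared
per-feature distance contributions are accumulated incrementally in
selection order, which is bit-identical to recomputing the subset distances
from scratch in the same order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset
from .graph import knn_adjacency, SampleGraph
from .modularity import ClassPartition, modularity_community


class SelectionError(ValueError):
    """Raised for invalid selection parameters."""


@dataclass
class SelectionTrace:
    """Ordered selected features with the Q reached at each greedy step."""

    selected: list[int]
    q_values: list[float]
    K: int
    ties: str = "expand"
    count_self: bool = False
    #: optional per-step map {candidate index: Q of S + {candidate}}
    candidate_log: list[dict[int, float]] | None = None
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.selected) != len(set(self.selected)):
            raise SelectionError("selected features must be distinct")
        if len(self.selected) != len(self.q_values):
            raise SelectionError("one Q value per greedy step is required")

    @property
    def selected_one_based(self) -> list[int]:
        return [j + 1 for j in self.selected]

    def to_dict(self) -> dict:
        out = {
            "selected": self.selected,
            "selected_one_based": self.selected_one_based,
            "q_values": self.q_values,
            "K": self.K,
            "ties": self.ties,
            "count_self": self.count_self,
        }
        if self.feature_names:
            out["feature_names"] = [self.feature_names[j] for j in self.selected]
        if self.candidate_log is not None:
            out["candidate_log"] = [
                {str(k + 1): v for k, v in step.items()} for step in self.candidate_log
            ]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        """Two-column TSV: rank (1-based), feature name (or 1-based index)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tfeature\n")
            for r, j in enumerate(self.selected, start=1):
                name = self.feature_names[j] if self.feature_names else str(j + 1)
                fh.write(f"{r}\t{name}\n")


def score_subset(
    ds: LabeledDataset,
    subset: Sequence[int],
    K: int,
    ties: str = "expand",
    count_self: bool = False,
) -> float:
    """Community modularity Q of the sample graph in ``subset``.

    Equals ``modularity_community(build_ksg(ds, subset, K), labels).Q``;
    implemented directly on the accumulated squared distances so the greedy
    selector and this scorer share one code path.
    """
    subset = [int(j) for j in subset]
    if not subset:
        raise SelectionError("subset must be non-empty")
    sq = _accumulate(ds.values, subset)
    return _score_sq(sq, ds, subset, K, ties, count_self)


def _accumulate(values: np.ndarray, subset: Sequence[int]) -> np.ndarray:
    m = values.shape[0]
    sq = np.zeros((m, m))
    for j in subset:
        diff = values[:, j, None] - values[None, :, j]
        sq += diff * diff
    return sq


def _score_sq(sq, ds, subset, K, ties, count_self) -> float:
    A = knn_adjacency(sq, K, ties=ties, count_self=count_self)
    g = SampleGraph(
        adjacency=A, K=K, feature_subset=tuple(subset), ties=ties, count_self=count_self
    )
    return modularity_community(g, ClassPartition.from_dataset(ds)).Q


def kfsgfs_select(
    ds: LabeledDataset,
    P: int,
    K: int = 2,
    ties: str = "expand",
    count_self: bool = False,
    record_candidates: bool = False,
) -> SelectionTrace:
    """Select P features by greedy forward maximization of graph modularity.

    Parameters
    ----------
    ds : LabeledDataset
    P : int
        Number of features to select, ``1 <= P <= n_features``.
    K : int, default 2
        Neighbor count of the sample graph (the value used throughout the
        experiments this method was developed on).
    ties, count_self
        Neighborhood convention, see :mod:`kfsgfs.graph`.
    record_candidates : bool
        If True, keep the Q of every candidate at every step.
    """
    n = ds.n_features
    if P <= 0:
        raise SelectionError("P must be positive")
    if P > n:
        raise SelectionError(f"P={P} exceeds the number of features n={n}")
    if not 1 <= K <= ds.n_samples - 1:
        raise SelectionError(f"K={K} invalid for m={ds.n_samples} samples")

    selected: list[int] = []
    q_values: list[float] = []
    log: list[dict[int, float]] | None = [] if record_candidates else None
    base_sq = np.zeros((ds.n_samples, ds.n_samples))

    for _ in range(P):
        best_f = -1
        best_q = -np.inf
        step_log: dict[int, float] = {}
        for f in range(n):  # ascending index; strict > keeps lowest on ties
            if f in selected:
                continue
            diff = ds.values[:, f, None] - ds.values[None, :, f]
            q = _score_sq(
                base_sq + diff * diff, ds, selected + [f], K, ties, count_self
            )
            if record_candidates:
                step_log[f] = q
            if q > best_q:
                best_q = q
                best_f = f
        diff = ds.values[:, best_f, None] - ds.values[None, :, best_f]
        base_sq += diff * diff
        selected.append(best_f)
        q_values.append(best_q)
        if log is not None:
            log.append(step_log)

    return SelectionTrace(
        selected=selected,
        q_values=q_values,
        K=K,
        ties=ties,
        count_self=count_self,
        candidate_log=log,
        feature_names=list(ds.feature_names),
    )
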