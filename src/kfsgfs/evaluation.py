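"""Classifier-based evaluation of a selected feature subset.

The reference protocol is 1-nearest-neighbor accuracy under stratified
tenfold cross-validation, averaged over 10 independently re-randomized
runs, on the columns of the selected subset. Accuracies are reported in
percent. A paired one-tailed t-test compares two methods' accuracy vectors.

Any other classifier can be plugged in through the ``classifier`` argument:
an object with ``fit(X, y)`` and ``predict(X)`` (the scikit-learn contract).
The default in-package classifier is exact 1-NN with Euclidean distance and
distance ties broken by the lowest training-sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .dataset import LabeledDataset


class EvaluationError(ValueError):
    """Raised for invalid evaluation parameters or degenerate tests."""


class OneNearestNeighbor:
    """Exact 1-NN, Euclidean, deterministic lowest-index tie-break."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneNearestNeighbor":
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2)
        # argmin returns the first (lowest training index) minimizer
        return self._y[np.argmin(d, axis=1)]


@dataclass
class CVReport:
    """Cross-validated accuracy of a classifier on a feature subset."""

    s: int  # number of features used
    fold_accuracies: np.ndarray  # runs x folds, percent
    run_means: np.ndarray  # per-run mean, percent
    mean_accuracy: float  # grand mean over runs, percent
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        acc = np.asarray(self.fold_accuracies, dtype=float)
        if ((acc < 0) | (acc > 100)).any():
            raise EvaluationError("accuracies must lie in [0, 100]")
        if abs(self.mean_accuracy - float(np.mean(self.run_means))) > 1e-9:
            raise EvaluationError("mean must equal the mean of per-run means")

    def to_dict(self) -> dict:
        return {
            "s": self.s,
            "mean_accuracy": self.mean_accuracy,
            "run_means": np.asarray(self.run_means).tolist(),
            "fold_accuracies": np.asarray(self.fold_accuracies).tolist(),
            "seeds": self.seeds,
        }


@dataclass
class TTestResult:
    """Paired one-tailed t-test outcome."""

    t: float
    df: int
    p_value: float
    alternative: str = "greater"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value < 1.0:
            raise EvaluationError("p-value must lie in (0, 1)")


def knn1_cross_val(
    ds: LabeledDataset,
    subset: Sequence[int],
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
    classifier=None,
) -> CVReport:
    """Stratified k-fold CV accuracy of a classifier on ``subset`` columns.

    Each run ``r`` re-randomizes the fold assignment with ``seed + r``.
    Stratification keeps per-class proportions within one sample per fold;
    when some class has fewer members than ``folds`` the split falls back to
    plain (unstratified) folds with a warning.

    Returns accuracies in percent; ``mean_accuracy`` is the mean of the
    per-run mean fold accuracies.
    """
    subset = [int(j) for j in subset]
    if not subset:
        raise EvaluationError("subset must be non-empty")
    if folds < 2:
        raise EvaluationError("folds must be >= 2")
    if folds > ds.n_samples:
        raise EvaluationError("more folds than samples")
    X = ds.values[:, subset]
    y = ds.labels
    stratified = np.bincount(y).min() >= folds
    if not stratified:
        warnings.warn(
            "a class has fewer members than folds; using plain K-fold",
            UserWarning,
            stacklevel=2,
        )
    fold_acc = np.empty((runs, folds))
    seeds = [seed + r for r in range(runs)]
    for r, run_seed in enumerate(seeds):
        splitter = (StratifiedKFold if stratified else KFold)(
            n_splits=folds, shuffle=True, random_state=run_seed
        )
        for k, (train, test) in enumerate(splitter.split(X, y)):
            clf = classifier if classifier is not None else OneNearestNeighbor()
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            fold_acc[r, k] = 100.0 * float(np.mean(pred == y[test]))
    run_means = fold_acc.mean(axis=1)
    return CVReport(
        s=len(subset),
        fold_accuracies=fold_acc,
        run_means=run_means,
        mean_accuracy=float(run_means.mean()),
        seeds=seeds,
    )


def paired_one_tailed_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired t-test of H1: mean(a - b) > 0, one-tailed.

    ``a`` and ``b`` are matched accuracy vectors (e.g. two selectors over the
    same dataset/size grid). Degrees of freedom are ``len(a) - 1``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired vectors must be 1-D of equal length")
    if len(a) < 2:
        raise EvaluationError("at least 2 pairs are required")
    d = a - b
    if np.ptp(d) == 0.0:
        raise EvaluationError("degenerate test: zero-variance differences")
    res = stats.ttest_rel(a, b, alternative="greater")
    return TTestResult(
        t=float(res.statistic), df=len(a) - 1, p_value=float(res.pvalue)
    )
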