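"""Labeled tabular datasets: loading, standardization, nine-level discretization.

The central container is :class:`LabeledDataset`, a dense feature matrix with
one integer class code per sample. Class codes are always ``0..n_classes-1``
in first-appearance order of the original label tokens, so every run over the
same file produces the same coding.

Two preprocessing steps mirror the usual treatment of continuous biomedical
data before graph construction and mutual-information estimation:

* :func:`standardize` — per-feature zero mean, unit (population) variance;
* :func:`discretize_nine_level` — map each feature to the nine integer levels
  ``-4..4`` using a central band of width sigma around the mean and four
  sigma-wide intervals on each side, truncating beyond.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class DatasetError(ValueError):
    """Raised for unreadable, empty, or malformed dataset inputs."""


def _recode_labels(tokens: Sequence) -> tuple[np.ndarray, list[str]]:
    """Map raw label tokens to codes 0..n_c-1 in first-appearance order."""
    seen: dict[str, int] = {}
    codes = np.empty(len(tokens), dtype=np.int64)
    for i, tok in enumerate(tokens):
        key = _label_token(tok)
        if key not in seen:
            seen[key] = len(seen)
        codes[i] = seen[key]
    return codes, list(seen)


def _label_token(tok) -> str:
    if isinstance(tok, float) and tok == int(tok):
        return str(int(tok))
    return str(tok)


@dataclass
class LabeledDataset:
    """Dense feature matrix with integer class labels.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Real-valued feature matrix, rows are samples.
    labels : ndarray of shape (m,)
        Integer class codes, exactly ``0..n_classes-1``.
    feature_names : list of str
        Unique identifier per column.
    class_names : list of str
        Original label tokens in first-appearance order; ``class_names[c]``
        is the token behind code ``c``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m == 0:
            raise DatasetError("zero samples")
        if n == 0:
            raise DatasetError("zero features")
        if self.labels.shape != (m,):
            raise DatasetError("labels length must equal the number of rows")
        if np.isnan(self.values).any():
            raise DatasetError("missing/NaN feature values are not supported")
        present = np.unique(self.labels)
        if len(present) < 2:
            raise DatasetError("at least 2 distinct classes are required")
        if present[0] != 0 or present[-1] != len(present) - 1:
            raise DatasetError("class codes must be exactly 0..n_classes-1")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(n)]
        if len(self.feature_names) != n:
            raise DatasetError("feature_names length must equal column count")
        if len(set(self.feature_names)) != n:
            raise DatasetError("feature_names must be unique")
        if not self.class_names:
            self.class_names = [str(c) for c in range(len(present))]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def replace_values(self, values: np.ndarray) -> "LabeledDataset":
        """A copy of this dataset with a new feature matrix, labels shared."""
        return LabeledDataset(
            values=np.asarray(values, dtype=float),
            labels=self.labels.copy(),
            feature_names=list(self.feature_names),
            class_names=list(self.class_names),
        )

    def to_csv(self, path: str | Path, label_column: str = "label") -> None:
        """Write the dataset as a headered CSV, labels as original tokens."""
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame[label_column] = [self.class_names[c] for c in self.labels]
        # %.17g round-trips IEEE doubles exactly
        frame.to_csv(path, index=False, float_format="%.17g")


def load_dataset(
    path: str | Path,
    dialect: str = "csv",
    label_column: str | int = "label",
) -> LabeledDataset:
    """Load a labeled dataset from sparse SVMlight/LIBSVM text or CSV.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"csv", "svmlight"}
        ``"svmlight"`` expects ``<label> <index>:<value> ...`` lines with
        1-based feature indices; unmentioned indices become 0.0.
        ``"csv"`` expects a header row.
    label_column : str or int
        For CSV only: label column selected by name or 0-based position.

    Returns
    -------
    LabeledDataset
        Labels re-coded to ``0..n_classes-1`` preserving first-appearance
        order of the original tokens.
    """
    path = Path(path)
    if not path.is_file():
        raise DatasetError(f"cannot read dataset file: {path}")
    if dialect == "svmlight":
        return _load_svmlight(path)
    if dialect == "csv":
        return _load_csv(path, label_column)
    raise DatasetError(f"unknown dialect: {dialect!r}")


def _load_svmlight(path: Path) -> LabeledDataset:
    from sklearn.datasets import load_svmlight_file

    try:
        X, y = load_svmlight_file(str(path), zero_based=False)
    except Exception as exc:  # sklearn raises bare ValueError on bad rows
        raise DatasetError(f"unreadable svmlight file {path}: {exc}") from exc
    if X.shape[0] == 0:
        raise DatasetError("zero samples")
    codes, class_names = _recode_labels(y.tolist())
    return LabeledDataset(values=X.toarray(), labels=codes, class_names=class_names)


def _load_csv(path: Path, label_column: str | int) -> LabeledDataset:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise DatasetError("zero samples") from exc
    if frame.shape[0] == 0:
        raise DatasetError("zero samples")
    if isinstance(label_column, int):
        if not 0 <= label_column < frame.shape[1]:
            raise DatasetError(f"label column index {label_column} out of range")
        label_name = frame.columns[label_column]
    else:
        if label_column not in frame.columns:
            raise DatasetError(f"csv is missing the label column {label_column!r}")
        label_name = label_column
    labels_raw = frame[label_name]
    features = frame.drop(columns=[label_name])
    try:
        values = features.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DatasetError(f"non-numeric feature value in {path}: {exc}") from exc
    codes, class_names = _recode_labels(labels_raw.tolist())
    return LabeledDataset(
        values=values,
        labels=codes,
        feature_names=[str(c) for c in features.columns],
        class_names=class_names,
    )


def standardize(ds: LabeledDataset) -> LabeledDataset:
    """Scale every feature to zero mean and unit population variance.

    Zero-variance columns cannot be scaled; they become all-zero and a
    ``UserWarning`` is emitted naming them.
    """
    mu = ds.values.mean(axis=0)
    sigma = ds.values.std(axis=0)  # population form (divide by m)
    flat = sigma == 0.0
    if flat.any():
        names = [ds.feature_names[j] for j in np.flatnonzero(flat)]
        warnings.warn(
            f"zero-variance features standardized to all-zero: {names}",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, sigma)
    out = (ds.values - mu) / safe
    out[:, flat] = 0.0
    return ds.replace_values(out)


@dataclass
class DiscretizationModel:
    """Per-feature nine-level discretization rule fitted on a dataset.

    The transform of a raw value x for feature j is::

        z = (x - mu_j) / sigma_j
        level = 0                       if |z| <= 1/2
              = sign(z) * min(4, ceil(|z| - 1/2))   otherwise

    i.e. a central band of width sigma maps to 0, the four sigma-wide
    intervals on each side map to +-1..+-4, and anything beyond is truncated
    to +-4. Zero-variance features map entirely to 0.
    """

    mu: np.ndarray
    sigma: np.ndarray
    levels: tuple[int, ...] = tuple(range(-4, 5))

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if (self.sigma < 0).any():
            raise DatasetError("sigma must be non-negative")

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.atleast_2d(np.asarray(values, dtype=float))
        safe = np.where(self.sigma == 0.0, 1.0, self.sigma)
        z = (values - self.mu) / safe
        z[:, self.sigma == 0.0] = 0.0
        mag = np.ceil(np.abs(z) - 0.5)
        out = np.where(np.abs(z) <= 0.5, 0.0, np.sign(z) * np.minimum(4.0, mag))
        return out.astype(np.int64)


def discretize_nine_level(
    ds: LabeledDataset,
) -> tuple[LabeledDataset, DiscretizationModel]:
    """Discretize every feature to the nine integer levels ``-4..4``.

    The per-feature mean and population standard deviation are estimated
    from ``ds`` itself. Returns the discretized dataset together with the
    fitted :class:`DiscretizationModel` so the same rule can be applied to
    held-out data.
    """
    mu = ds.values.mean(axis=0)
    sigma = ds.values.std(axis=0)
    if (sigma == 0.0).any():
        names = [ds.feature_names[j] for j in np.flatnonzero(sigma == 0.0)]
        warnings.warn(
            f"zero-variance features discretize to all-zero: {names}",
            UserWarning,
            stacklevel=2,
        )
    model = DiscretizationModel(mu=mu, sigma=sigma)
    return ds.replace_values(model.transform(ds.values).astype(float)), model
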