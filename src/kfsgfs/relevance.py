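"""Plug-in (conditional) mutual information on discrete vectors.

The relevant-independency diagnostic between features is
``RI(f_i, C; f_j) = I(f_i; C | f_j)``: the information f_i still carries
about the class once f_j is known. All estimates are maximum-likelihood
("plug-in") on the empirical contingency counts with the 0*log0 = 0
convention; continuous features must be discretized first (the nine-level
scheme in :func:`kfsgfs.dataset.discretize_nine_level` is the one used
throughout this package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset


@dataclass
class CMIEstimate:
    """A (conditional) mutual-information value with its support counts."""

    value: float
    base: float
    #: joint contingency counts over (x, c, z) cells actually observed
    counts: dict[tuple, int]

    def __post_init__(self) -> None:
        if self.value < -1e-12:
            raise ValueError("plug-in (C)MI cannot be negative")
        self.value = max(self.value, 0.0)


def _encode(v) -> np.ndarray:
    v = np.asarray(v)
    if v.ndim != 1:
        raise ValueError("inputs must be 1-D vectors")
    _, codes = np.unique(v, return_inverse=True)
    return codes


def conditional_mi(x, c, z=None, base: float = 2.0) -> CMIEstimate:
    """I(x; c | z), or plain I(x; c) when ``z`` is None.

    Parameters
    ----------
    x, c, z : 1-D discrete (integer-coded) vectors of equal length
        ``z`` may be omitted for the unconditional mutual information.
    base : {2.0, e}
        Logarithm base; 2 gives bits, ``numpy.e`` gives nats.
    """
    x = _encode(x)
    c = _encode(c)
    if len(x) == 0:
        raise ValueError("empty vectors")
    if len(x) != len(c):
        raise ValueError("length mismatch between x and c")
    if z is None:
        z = np.zeros(len(x), dtype=np.int64)
    else:
        z = _encode(z)
        if len(z) != len(x):
            raise ValueError("length mismatch between x and z")

    n = len(x)
    nx, nc, nz = x.max() + 1, c.max() + 1, z.max() + 1
    joint = np.zeros((nx, nc, nz))
    np.add.at(joint, (x, c, z), 1.0)

    n_xz = joint.sum(axis=1)  # (x, z)
    n_cz = joint.sum(axis=0)  # (c, z)
    n_z = joint.sum(axis=(0, 1))  # (z,)

    mask = joint > 0
    xs, cs, zs = np.nonzero(mask)
    terms = joint[mask] / n * np.log(
        joint[mask] * n_z[zs] / (n_xz[xs, zs] * n_cz[cs, zs])
    )
    value = float(terms.sum() / np.log(base))
    counts = {
        (int(a), int(b), int(d)): int(joint[a, b, d]) for a, b, d in zip(xs, cs, zs)
    }
    return CMIEstimate(value=value, base=base, counts=counts)


def mutual_information(x, c, base: float = 2.0) -> CMIEstimate:
    """Plain plug-in mutual information I(x; c)."""
    return conditional_mi(x, c, z=None, base=base)


def ri_table(
    ds_discrete: LabeledDataset, conditioning_feature: int, base: float = 2.0
) -> dict[str, float]:
    """RI(f_i, C; f_j) for every feature i != j, j = ``conditioning_feature``.

    ``ds_discrete`` must already hold integer-coded values (e.g. the output
    of :func:`kfsgfs.dataset.discretize_nine_level`). Keys are feature names.
    """
    j = int(conditioning_feature)
    if not 0 <= j < ds_discrete.n_features:
        raise ValueError(f"conditioning feature index out of range: {j}")
    zj = ds_discrete.values[:, j]
    out: dict[str, float] = {}
    for i in range(ds_discrete.n_features):
        if i == j:
            continue
        est = conditional_mi(ds_discrete.values[:, i], ds_discrete.labels, zj, base)
        out[ds_discrete.feature_names[i]] = est.value
    return out
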