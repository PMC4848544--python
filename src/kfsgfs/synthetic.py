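"""Synthetic labeled datasets with group-informative (XOR-like) structure.

The generator emulates the three feature archetypes that matter for
subset-level feature selection:

* **XOR pairs** — two features whose *sign pattern* jointly determines the
  class (same signs vs. opposite signs), drawn exactly balanced within each
  class so that each feature's discretized marginal carries no class
  information on its own. A fine-scale class offset, far below the
  nine-level discretization resolution, additionally separates classes
  within each sign mode: the pair is invisible to per-feature
  mutual-information ranking yet geometrically class-separated, which is the
  regime a sample-graph criterion is built to detect.
* **Individually informative features** — class-shifted Gaussians.
* **Redundant copies** — an informative feature plus small noise.
* **Pure noise** — standard Gaussians independent of the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DatasetError, LabeledDataset

#: Separation (in feature units, features have scale ~1) between the class
#: means of individually informative features.
INFORMATIVE_SEPARATION = 1.5

#: Fine-scale within-mode class offset on XOR features. Far below the
#: nine-level bin width (~1 sigma), so discretized marginals stay
#: class-agnostic while nearest neighbors become class-pure.
XOR_CLASS_OFFSET = 0.08


@dataclass(frozen=True)
class SyntheticSpec:
    """Composition of a synthetic dataset; a seed fixes the output exactly."""

    samples_per_class: int = 200
    n_classes: int = 2
    n_xor_pairs: int = 1
    n_informative: int = 2
    n_redundant: int = 1
    n_noise: int = 8
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.samples_per_class,
            self.n_xor_pairs,
            self.n_informative,
            self.n_redundant,
            self.n_noise,
        )
        if any(c < 0 for c in counts):
            raise DatasetError("all counts must be >= 0")
        if self.n_classes < 2:
            raise DatasetError("class count must be >= 2")
        if self.samples_per_class < 1:
            raise DatasetError("samples_per_class must be >= 1")
        if self.n_features == 0:
            raise DatasetError("total features must be >= 1")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise DatasetError("redundant copies require informative features")
        if self.noise_sd < 0:
            raise DatasetError("noise_sd must be >= 0")

    @property
    def n_features(self) -> int:
        return 2 * self.n_xor_pairs + self.n_informative + self.n_redundant + self.n_noise


def _balanced_signs(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """Random +-1 per sample, exactly balanced within each class."""
    signs = np.empty(len(labels))
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        half = len(idx) // 2
        pattern = np.concatenate([np.ones(half), -np.ones(len(idx) - half)])
        signs[idx] = rng.permutation(pattern)
    return signs


def generate_synthetic(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a :class:`LabeledDataset` following ``spec``.

    Column order: XOR pairs, informative, redundant, noise; names encode the
    archetype (``xor1_a``, ``xor1_b``, ``inf1``, ``red1``, ``noise1``, ...).
    Deterministic for a fixed spec (the seed is part of the spec).
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(spec.n_classes), spec.samples_per_class)
    m = len(labels)
    parity = np.where(labels % 2 == 0, 1.0, -1.0)

    columns: list[np.ndarray] = []
    names: list[str] = []
    for p in range(spec.n_xor_pairs):
        s1 = _balanced_signs(rng, labels)
        s2 = s1 * parity  # sign product encodes the class parity
        offset = XOR_CLASS_OFFSET * labels
        columns.append(s1 + offset + rng.normal(0.0, spec.noise_sd, m))
        columns.append(s2 + offset + rng.normal(0.0, spec.noise_sd, m))
        names += [f"xor{p + 1}_a", f"xor{p + 1}_b"]

    informative: list[np.ndarray] = []
    for j in range(spec.n_informative):
        col = INFORMATIVE_SEPARATION * labels + rng.normal(0.0, 1.0, m)
        informative.append(col)
        columns.append(col)
        names.append(f"inf{j + 1}")

    for j in range(spec.n_redundant):
        src = informative[j % len(informative)]
        columns.append(src + rng.normal(0.0, spec.noise_sd, m))
        names.append(f"red{j + 1}")

    for j in range(spec.n_noise):
        columns.append(rng.normal(0.0, 1.0, m))
        names.append(f"noise{j + 1}")

    return LabeledDataset(
        values=np.column_stack(columns),
        labels=labels,
        feature_names=names,
        class_names=[f"class_{c}" for c in range(spec.n_classes)],
    )


def xor_feature_indices(spec: SyntheticSpec) -> list[int]:
    """Column indices of the XOR features under the generator's layout."""
    return list(range(2 * spec.n_xor_pairs))


def noise_feature_indices(spec: SyntheticSpec) -> list[int]:
    """Column indices of the pure-noise features."""
    start = 2 * spec.n_xor_pairs + spec.n_informative + spec.n_redundant
    return list(range(start, start + spec.n_noise))
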