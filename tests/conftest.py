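import numpy as np
import pytest
from hypothesis import settings

import kfsgfs as kf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def iris_raw() -> kf.LabeledDataset:
    """The 150x4 iris dataset with its standard feature order."""
    from sklearn.datasets import load_iris

    X, y = load_iris(return_X_y=True)
    return kf.LabeledDataset(
        values=X,
        labels=y,
        feature_names=["f1", "f2", "f3", "f4"],
        class_names=["setosa", "versicolor", "virginica"],
    )


@pytest.fixture(scope="session")
def iris_std(iris_raw) -> kf.LabeledDataset:
    return kf.standardize(iris_raw)


@pytest.fixture(scope="session")
def iris_discrete(iris_raw) -> kf.LabeledDataset:
    ds, _ = kf.discretize_nine_level(iris_raw)
    return ds


def xor_benchmark(seed: int) -> tuple[kf.LabeledDataset, kf.SyntheticSpec]:
    """Two XOR features + eight pure-noise features, 200 samples per class."""
    spec = kf.SyntheticSpec(
        samples_per_class=200,
        n_classes=2,
        n_xor_pairs=1,
        n_informative=0,
        n_redundant=0,
        n_noise=8,
        seed=seed,
    )
    return kf.generate_synthetic(spec), spec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
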