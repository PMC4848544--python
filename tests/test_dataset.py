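"""Loading, standardization and nine-level discretization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import kfsgfs as kf
from kfsgfs.dataset import DatasetError


class TestLoadDataset:
    def test_svmlight_sparse_text(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("1 1:0.5 3:-1.0\n2 2:2.0\n")
        ds = kf.load_dataset(p, dialect="svmlight")
        np.testing.assert_allclose(ds.values, [[0.5, 0, -1.0], [0, 2.0, 0]])
        assert ds.labels.tolist() == [0, 1]
        assert ds.class_names == ["1", "2"]

    def test_empty_file_is_zero_samples(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(DatasetError, match="zero samples"):
            kf.load_dataset(p, dialect="svmlight")
        with pytest.raises(DatasetError, match="zero samples"):
            kf.load_dataset(p, dialect="csv")

    def test_csv_label_by_name_and_position(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b,species\n1.0,2.0,cat\n3.0,4.0,dog\n")
        by_name = kf.load_dataset(p, dialect="csv", label_column="species")
        by_pos = kf.load_dataset(p, dialect="csv", label_column=2)
        np.testing.assert_array_equal(by_name.values, by_pos.values)
        assert by_name.class_names == ["cat", "dog"]
        assert by_name.feature_names == ["a", "b"]

    def test_csv_missing_label_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(DatasetError, match="label column"):
            kf.load_dataset(p, dialect="csv", label_column="species")

    def test_csv_non_numeric_feature(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,label\noops,x\n2.0,y\n")
        with pytest.raises(DatasetError, match="non-numeric"):
            kf.load_dataset(p, dialect="csv", label_column="label")

    def test_csv_round_trip(self, tmp_path, rng):
        ds = kf.LabeledDataset(
            values=rng.normal(size=(7, 3)),
            labels=np.array([0, 1, 2, 0, 1, 2, 0]),
            feature_names=["x", "y", "z"],
            class_names=["a", "b", "c"],
        )
        p = tmp_path / "rt.csv"
        ds.to_csv(p)
        back = kf.load_dataset(p, dialect="csv", label_column="label")
        np.testing.assert_array_equal(back.values, ds.values)
        assert back.labels.tolist() == ds.labels.tolist()
        assert back.class_names == ds.class_names


class TestInvariants:
    def test_rejects_nan(self):
        with pytest.raises(DatasetError, match="NaN"):
            kf.LabeledDataset(values=[[np.nan], [1.0]], labels=[0, 1])

    def test_rejects_single_class(self):
        with pytest.raises(DatasetError, match="2 distinct classes"):
            kf.LabeledDataset(values=[[1.0], [2.0]], labels=[0, 0])

    def test_rejects_gappy_codes(self):
        with pytest.raises(DatasetError, match="0..n_classes-1"):
            kf.LabeledDataset(values=[[1.0], [2.0]], labels=[0, 2])

    def test_rejects_duplicate_feature_names(self):
        with pytest.raises(DatasetError, match="unique"):
            kf.LabeledDataset(
                values=[[1.0, 2.0], [3.0, 4.0]], labels=[0, 1],
                feature_names=["a", "a"],
            )


class TestStandardize:
    def test_two_point_column(self):
        ds = kf.LabeledDataset(values=[[0.0], [2.0]], labels=[0, 1])
        out = kf.standardize(ds)
        np.testing.assert_allclose(out.values, [[-1.0], [1.0]])

    def test_idempotent(self, rng):
        ds = kf.LabeledDataset(
            values=rng.normal(size=(50, 5)), labels=rng.integers(0, 2, 50)
        )
        once = kf.standardize(ds)
        twice = kf.standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_moments(self, rng):
        ds = kf.LabeledDataset(
            values=rng.normal(3.0, 7.0, size=(50, 5)), labels=rng.integers(0, 2, 50)
        )
        out = kf.standardize(ds)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.abs(out.values.var(axis=0) - 1.0).max() < 1e-10

    def test_zero_variance_column_warns_and_zeroes(self):
        ds = kf.LabeledDataset(
            values=[[1.0, 5.0], [2.0, 5.0]], labels=[0, 1], feature_names=["a", "b"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = kf.standardize(ds)
        np.testing.assert_array_equal(out.values[:, 1], [0.0, 0.0])


class TestDiscretizeNineLevel:
    @pytest.mark.parametrize(
        "z, level",
        [
            (0.0, 0),  # the mean itself
            (0.5, 0),  # central band is closed
            (0.75, 1),  # inside (mu + s/2, mu + 3s/2]
            (1.5, 1),
            (1.6, 2),
            (-0.75, -1),
            (10.0, 4),  # truncation
            (-10.0, -4),
        ],
    )
    def test_band_mapping(self, z, level):
        # a column with mean 0, population sigma 1, plus the probe value at
        # the end; the probe barely perturbs the moments of a long column
        base = np.concatenate([np.tile([-1.0, 1.0], 500), [z]])
        model = kf.DiscretizationModel(mu=np.zeros(1), sigma=np.ones(1))
        assert model.transform(base[:, None])[-1, 0] == level

    def test_alphabet_and_fit(self, rng):
        ds = kf.LabeledDataset(
            values=rng.normal(size=(200, 4)) * 10, labels=rng.integers(0, 3, 200)
        )
        out, model = kf.discretize_nine_level(ds)
        assert set(np.unique(out.values)) <= set(range(-4, 5))
        np.testing.assert_array_equal(
            out.values, model.transform(ds.values).astype(float)
        )

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30))
    def test_monotone_in_raw_value(self, raw):
        model = kf.DiscretizationModel(mu=np.array([3.0]), sigma=np.array([2.0]))
        x = np.sort(np.asarray(raw))
        levels = model.transform(x[:, None])[:, 0]
        assert (np.diff(levels) >= 0).all()

    def test_zero_variance_maps_to_zero(self):
        ds = kf.LabeledDataset(values=[[5.0, 1.0], [5.0, 2.0]], labels=[0, 1])
        with pytest.warns(UserWarning, match="zero-variance"):
            out, _ = kf.discretize_nine_level(ds)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0])
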