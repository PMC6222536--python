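import numpy as np
import pytest

from cytofeat import (
    CytokineSVC,
    grid_search,
    kfold_cv,
    load_model,
    ratio_split,
    repeated_cv,
    save_model,
    train,
)
from cytofeat.errors import (
    CompositionError,
    SchemaError,
    TrainingError,
    ValidationError,
)
from cytofeat.evaluate import fold_assignment
from cytofeat.types import FeatureMatrix


def blobs(n_pos=50, n_neg=50, sep=4.0, dim=18, seed=0, schema="sss18"):
    """Two spherical Gaussian clusters as a labeled feature matrix."""
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=+sep / 2, size=(n_pos, dim))
    neg = rng.normal(loc=-sep / 2, size=(n_neg, dim))
    values = np.vstack([pos, neg])
    labels = np.array([1] * n_pos + [-1] * n_neg)
    ids = [f"b{i}" for i in range(n_pos + n_neg)]
    return FeatureMatrix(ids=ids, values=values, schema=schema, labels=labels)


class TestCytokineSVC:
    def test_separable_training_accuracy(self):
        fm = blobs(sep=6.0)
        model = train(fm, kernel="linear")
        assert np.mean(model.predict(fm.values) == fm.labels) == 1.0

    def test_single_class_rejected(self):
        fm = blobs()
        with pytest.raises(TrainingError):
            CytokineSVC().fit(fm.values[:50], fm.labels[:50])

    def test_gamma_required_for_gaussian(self):
        fm = blobs()
        with pytest.raises(ValidationError, match="gamma"):
            train(fm, kernel="gaussian")

    def test_gamma_rejected_for_linear(self):
        fm = blobs()
        with pytest.raises(ValidationError, match="gamma"):
            train(fm, kernel="linear", gamma=0.1)

    def test_dimension_mismatch_at_predict(self):
        fm = blobs()
        model = train(fm)
        with pytest.raises(SchemaError):
            model.predict(fm.values[:, :5])

    def test_duplicated_rows_same_predictions(self):
        fm = blobs(n_pos=20, n_neg=20, sep=2.0)
        probe = blobs(n_pos=10, n_neg=10, sep=2.0, seed=9).values
        m1 = CytokineSVC(C=1.0).fit(fm.values, fm.labels)
        doubled = np.vstack([fm.values, fm.values])
        labels2 = np.concatenate([fm.labels, fm.labels])
        m2 = CytokineSVC(C=1.0).fit(doubled, labels2)
        np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))

    def test_shuffled_labels_near_chance(self):
        """Permutation null: CV accuracy within 3 SD of 0.5 on balanced data."""
        rng = np.random.default_rng(3)
        fm = blobs(n_pos=50, n_neg=50, sep=4.0, seed=3)
        shuffled = FeatureMatrix(
            ids=fm.ids,
            values=fm.values,
            schema=fm.schema,
            labels=rng.permutation(fm.labels),
        )
        result = kfold_cv(shuffled, k=10, seed=0)
        # binomial SD of a fold accuracy mean at p=0.5, n=100 predictions
        assert abs(result.mean["acc"] - 0.5) < 3 * 0.05


class TestFoldAssignment:
    def test_sizes_differ_by_at_most_one(self):
        labels = np.array([1] * 17 + [-1] * 26)
        assign = fold_assignment(labels, k=5, seed=1)
        sizes = np.bincount(assign, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_stratified_class_balance(self):
        labels = np.array([1] * 10 + [-1] * 90)
        assign = fold_assignment(labels, k=10, seed=2)
        for fold in range(10):
            assert np.sum(labels[assign == fold] == 1) == 1

    def test_deterministic(self):
        labels = np.array([1, -1] * 20)
        a = fold_assignment(labels, 4, seed=7)
        b = fold_assignment(labels, 4, seed=7)
        np.testing.assert_array_equal(a, b)


class TestKfoldCV:
    def test_partition_arithmetic(self):
        fm = blobs(n_pos=50, n_neg=50)
        result = kfold_cv(fm, k=10, seed=0)
        assert len(result.fold_reports) == 10
        assert sum(r.counts.total for r in result.fold_reports) == 100
        assert all(r.counts.total == 10 for r in result.fold_reports)

    def test_perfect_separation(self):
        result = kfold_cv(blobs(sep=8.0), k=10, seed=0)
        assert result.mean["acc"] == 1.0

    def test_same_seed_reproducible(self):
        fm = blobs(sep=1.0)
        a = kfold_cv(fm, k=5, seed=4)
        b = kfold_cv(fm, k=5, seed=4)
        assert a.mean == b.mean and a.sd == b.sd

    def test_leave_one_out_tests_every_item(self):
        fm = blobs(n_pos=8, n_neg=8, sep=6.0)
        result = kfold_cv(fm, k=16, seed=0, stratified=False)
        assert sum(r.counts.total for r in result.fold_reports) == 16
        assert all(r.counts.total == 1 for r in result.fold_reports)

    def test_stratification_guard(self):
        fm = blobs(n_pos=5, n_neg=50)
        with pytest.raises(ValidationError, match="fewer than k"):
            kfold_cv(fm, k=10)


class TestRepeatedCV:
    def test_reproducible_from_base_seed(self):
        fm = blobs(sep=1.5)
        a = repeated_cv(fm, k=5, reps=2, base_seed=11)
        b = repeated_cv(fm, k=5, reps=2, base_seed=11)
        assert a.rep_means == b.rep_means
        assert a.repetitions[0].seed == 11 and a.repetitions[1].seed == 12

    def test_perfect_separation_all_reps(self):
        result = repeated_cv(blobs(sep=8.0), k=5, reps=3, base_seed=0)
        assert all(m["acc"] == 1.0 for m in result.rep_means)
        assert result.overall_sd["acc"] == 0.0


class TestGridSearch:
    def test_single_cell(self):
        result = grid_search(blobs(), c_values=(1.0,), gamma_values=(1.0,), seed=0)
        assert result.surface.shape == (1, 1)
        assert (result.best_c, result.best_gamma) == (1.0, 1.0)

    def test_default_grid_is_121_cells(self):
        result = grid_search(blobs(n_pos=15, n_neg=15), inner_k=2, seed=0)
        assert result.surface.shape == (11, 11)
        assert result.surface.size == 121
        assert result.best_accuracy == result.surface.max()

    def test_flat_surface_tie_breaks_to_smallest(self):
        # identical rows -> every cell trains on the same degenerate geometry
        values = np.tile(np.ones(18), (20, 1))
        fm = FeatureMatrix(
            ids=[f"d{i}" for i in range(20)],
            values=values,
            schema="sss18",
            labels=np.array([1] * 10 + [-1] * 10),
        )
        result = grid_search(
            fm, c_values=(0.5, 1.0, 2.0), gamma_values=(0.25, 0.5), inner_k=2, seed=0
        )
        assert np.allclose(result.surface, result.surface[0, 0])
        assert (result.best_c, result.best_gamma) == (0.5, 0.25)

    def test_best_cell_attains_surface_max(self):
        result = grid_search(
            blobs(sep=2.0), c_values=(0.1, 1.0, 10.0), gamma_values=(0.01, 0.1), seed=1
        )
        ci = result.c_values.index(result.best_c)
        gi = result.gamma_values.index(result.best_gamma)
        assert result.surface[ci, gi] == result.surface.max()


class TestRatioSplit:
    def test_one_to_nine_arithmetic(self):
        fm = blobs(n_pos=100, n_neg=900, sep=1.0)
        train_m, test_m = ratio_split(fm, positive_fraction=0.1, test_fraction=0.2)
        assert test_m.n_samples == 200
        assert int(np.sum(test_m.labels == 1)) == 20
        assert train_m.n_samples == 800
        assert int(np.sum(train_m.labels == 1)) == 80
        assert set(train_m.ids) | set(test_m.ids) == set(fm.ids)
        assert not set(train_m.ids) & set(test_m.ids)

    def test_balanced_stratified(self):
        fm = blobs(n_pos=50, n_neg=50)
        train_m, test_m = ratio_split(fm, 0.5, 0.2, seed=3)
        assert int(np.sum(test_m.labels == 1)) == 10

    def test_infeasible_ratio(self):
        fm = blobs(n_pos=10, n_neg=10)
        with pytest.raises(CompositionError):
            ratio_split(fm, positive_fraction=0.1, test_fraction=0.2)


class TestModelPersistence:
    @pytest.mark.parametrize("kernel,gamma", [("linear", None), ("gaussian", 0.05)])
    def test_roundtrip_predictions(self, tmp_path, kernel, gamma):
        fm = blobs(sep=2.0)
        probe = blobs(sep=2.0, seed=8)
        model = train(fm, kernel=kernel, gamma=gamma)
        path = tmp_path / "m.libsvm"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            loaded.predict(probe.values), model.predict(probe.values)
        )
        np.testing.assert_allclose(
            loaded.decision_function(probe.values),
            model.decision_function(probe.values),
            atol=1e-9,
        )
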