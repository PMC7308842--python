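"""LOSO protocol, confusion-matrix metrics, sweeps, leakage protection."""

import numpy as np
import pytest

import leanhar as lh
from leanhar.evaluation import device_subsets
from leanhar.reference import daliac_reference_confusion


class TestLosoSplit:
    def test_19_subjects_19_folds(self):
        folds = lh.loso_split([f"s{i}" for i in range(19)])
        assert len(folds) == 19
        for train, test in folds:
            assert test not in train and len(train) == 18

    def test_two_subjects(self):
        folds = lh.loso_split(["a", "b"])
        assert folds == [(["b"], "a"), (["a"], "b")]

    def test_test_sets_partition_subjects(self):
        ids = ["a", "b", "c", "a", "b"]
        folds = lh.loso_split(ids)
        assert [t for _, t in folds] == ["a", "b", "c"]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            lh.loso_split(["only", "only"])


class TestConfusionMetrics:
    def test_identity_matrix_is_perfect(self):
        cm = lh.ConfusionMatrix(np.eye(4, dtype=int) * 10, list("abcd"))
        m = lh.confusion_metrics(cm)
        assert (m == 1.0).all().all()
        assert cm.accuracy == 1.0

    def test_reference_matrix_spot_values(self):
        m = lh.confusion_metrics(daliac_reference_confusion()).round(3)
        assert m.loc["sit", "precision"] == 0.993
        assert m.loc["sit", "recall"] == 0.956
        assert m.loc["stand", "precision"] == 0.940
        assert m.loc["walk", "recall"] == 0.985
        assert m.loc["vacuum", "f_score"] == 0.927
        assert m.loc["jump", "recall"] == 1.000

    def test_zero_denominator_warns_and_zeroes(self):
        counts = np.array([[5, 0, 0], [2, 0, 0], [0, 0, 3]])
        cm = lh.ConfusionMatrix(counts, list("xyz"))
        with pytest.warns(UserWarning):
            m = lh.confusion_metrics(cm)
        assert m.loc["y", "precision"] == 0.0
        assert m.loc["y", "recall"] == 0.0
        assert m.loc["y", "f_score"] == 0.0

    def test_aggregation_addition(self):
        a = lh.ConfusionMatrix(np.array([[1, 0], [0, 1]]), ["p", "q"])
        b = lh.ConfusionMatrix(np.array([[2, 1], [0, 3]]), ["p", "q"])
        np.testing.assert_array_equal((a + b).counts, [[3, 1], [0, 4]])


@pytest.fixture(scope="module")
def result(small_features):
    spec = lh.default_daliac_hierarchy(use_codes=True)
    return lh.loso_from_features(small_features, spec, lh.LearnerSpec("lr"),
                                 seed=0)


class TestRunLoso:
    def test_mean_is_fold_mean(self, result):
        assert result.mean_accuracy == pytest.approx(
            np.mean(result.fold_accuracies), abs=1e-12
        )
        assert result.sd_accuracy == pytest.approx(
            np.std(result.fold_accuracies), abs=1e-12
        )

    def test_aggregated_matrix_totals(self, result, small_features):
        assert result.confusion.total == small_features.shape[0]
        assert 0.0 <= result.confusion.accuracy <= 1.0

    def test_base_accuracy_bounds_overall(self, result):
        # a wrong meta-class forces a wrong final label
        assert result.subtask_accuracies["base"]["mean"] >= result.mean_accuracy

    def test_fold_order_invariance(self, small_features):
        spec = lh.default_daliac_hierarchy(use_codes=True)
        fm = small_features
        order = np.argsort(fm.subject_ids, kind="stable")[::-1]
        reordered = lh.FeatureMatrix(
            X=fm.X[order], columns=fm.columns,
            labels=fm.labels[order], subject_ids=fm.subject_ids[order],
        )
        res = lh.loso_from_features(reordered, spec, lh.LearnerSpec("lr"), seed=0)
        ref = lh.loso_from_features(fm, spec, lh.LearnerSpec("lr"), seed=0)
        assert res.mean_accuracy == pytest.approx(ref.mean_accuracy, abs=1e-12)
        assert res.sd_accuracy == pytest.approx(ref.sd_accuracy, abs=1e-12)

    def test_result_serialization(self, result, tmp_path):
        result.save(tmp_path)
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "confusion_matrix.csv").exists()
        assert (tmp_path / "per_class_metrics.csv").exists()

    def test_no_leakage_from_test_subject(self):
        # corrupting one subject's raw data must not change the feature rows
        # of any other subject (preprocessing is strictly per recording)
        ds = lh.default_benchmark(3, seed=5, duration_s=15.0)
        bundles = [lh.preprocess(r) for r in ds.recordings]
        fm_ref = lh.build_feature_matrix(bundles)

        corrupted = []
        for r in ds.recordings:
            if r.subject_id == "S03":
                r = lh.SensorRecording(
                    subject_id=r.subject_id,
                    device_location=r.device_location,
                    sampling_rate_hz=r.sampling_rate_hz,
                    acc=r.acc * 10 + 3, gyro=r.gyro * 5, labels=r.labels,
                )
            corrupted.append(r)
        fm_bad = lh.build_feature_matrix([lh.preprocess(r) for r in corrupted])
        others = fm_ref.subject_ids != "S03"
        np.testing.assert_array_equal(fm_ref.X[others], fm_bad.X[others])


class TestCombinationSweep:
    def test_four_locations_give_15_subsets(self):
        assert len(device_subsets(["ankle", "chest", "hip", "wrist"])) == 15

    def test_two_locations_give_3_subsets(self):
        assert device_subsets(["b", "a"]) == [("a",), ("b",), ("a", "b")]

    def test_sweep_rows_and_ordering(self):
        ds = lh.default_benchmark(2, seed=9, duration_s=15.0,
                                  locations=("ankle", "wrist"))
        spec = lh.default_daliac_hierarchy(use_codes=True)
        table = lh.combination_sweep(ds.recordings, spec, lh.LearnerSpec("knn"),
                                     seed=0)
        assert len(table) == 6  # 3 subsets x {gyro, no gyro}
        assert table["devices"].value_counts().eq(2).all()
        assert table["n_devices"].is_monotonic_increasing
        assert table["mean_accuracy"].between(0, 1).all()
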