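"""Hierarchy specification and the two-level classifier."""

import numpy as np
import pytest

import leanhar as lh
from leanhar.hierarchy import DALIAC_ACTIVITIES


def _separable_data(rng, n_classes=6, n_per_class=30, n_features=12, margin=6.0):
    centers = rng.normal(scale=margin, size=(n_classes, n_features))
    X = np.vstack([
        centers[c] + rng.normal(size=(n_per_class, n_features))
        for c in range(n_classes)
    ])
    y = np.repeat(np.arange(n_classes), n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestHierarchySpec:
    def test_default_daliac_partition(self):
        spec = lh.default_daliac_hierarchy()
        assert sorted(spec.activities) == sorted(DALIAC_ACTIVITIES)
        assert len(spec.activities) == 13
        sizes = sorted(len(mc.members) for mc in spec.non_singletons)
        assert sizes == [2, 2, 2, 3]
        assert len(spec.meta_classes) == 8

    def test_union_is_disjoint_cover(self):
        spec = lh.default_daliac_hierarchy(use_codes=True)
        all_members = [m for mc in spec.meta_classes for m in mc.members]
        assert sorted(all_members) == list(range(1, 14))

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            lh.HierarchySpec((
                lh.MetaClass("a", (1, 2)), lh.MetaClass("b", (2, 3)),
            ))

    def test_flat_spec_is_all_singletons(self):
        spec = lh.HierarchySpec.flat([3, 1, 2, 1])
        assert all(mc.is_singleton for mc in spec.meta_classes)
        assert spec.activities == (1, 2, 3)

    def test_serialization_roundtrip(self, tmp_path):
        spec = lh.default_daliac_hierarchy(use_codes=True)
        for name in ("h.json", "h.yaml"):
            spec.save(tmp_path / name)
            loaded = lh.HierarchySpec.load(tmp_path / name)
            assert loaded.to_dict() == spec.to_dict()


class TestHierarchicalClassifier:
    SPEC = lh.HierarchySpec((
        lh.MetaClass("low", (0, 1)),
        lh.MetaClass("mid", (2,)),
        lh.MetaClass("high", (3, 4, 5)),
    ))

    def test_containment_invariant(self, rng):
        X, y = _separable_data(rng)
        model = lh.HierarchicalClassifier(self.SPEC, "lr").fit(X, y)
        Xr = rng.normal(scale=10, size=(500, X.shape[1]))
        meta = model.predict_meta(Xr)
        pred = model.predict(Xr)
        members = {mc.name: set(mc.members) for mc in self.SPEC.meta_classes}
        assert all(p in members[m] for p, m in zip(pred, meta))

    def test_flat_equals_direct_multiclass(self, rng):
        X, y = _separable_data(rng, margin=1.0)
        flat = lh.HierarchySpec.flat(y)
        hier = lh.HierarchicalClassifier(flat, "lr", random_state=3).fit(X, y)
        direct = lh.LearnerSpec("lr").make(3).fit(X, y)
        Xr = rng.normal(size=(300, X.shape[1]))
        np.testing.assert_array_equal(hier.predict(Xr), direct.predict(Xr))
        assert hier.sub_models == {}

    def test_single_meta_class_equals_flat_multiclass(self, rng):
        X, y = _separable_data(rng)
        one = lh.HierarchySpec((lh.MetaClass("all", tuple(range(6))),))
        with pytest.raises(ValueError, match="at least 2 meta-classes"):
            lh.HierarchicalClassifier(one, "lr").fit(X, y)
        # with a second (singleton) meta-class present the sub-model is a
        # plain multiclass fit over the big group
        two = lh.HierarchySpec((
            lh.MetaClass("rest", tuple(range(5))), lh.MetaClass("five", (5,)),
        ))
        model = lh.HierarchicalClassifier(two, "lr", random_state=0).fit(X, y)
        assert set(model.sub_models) == {"rest"}

    def test_singleton_passthrough(self, rng):
        X, y = _separable_data(rng)
        model = lh.HierarchicalClassifier(self.SPEC, "lr").fit(X, y)
        meta = model.predict_meta(X)
        pred = model.predict(X)
        assert np.all(pred[meta == "mid"] == 2)

    def test_memorizing_learner_reproduces_training_labels(self, rng):
        X, y = _separable_data(rng, margin=0.5)  # heavily overlapping
        knn1 = lh.LearnerSpec("knn", {"n_neighbors": 1})
        model = lh.HierarchicalClassifier(
            self.SPEC, knn1, task_learners={"base": knn1}
        ).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_undersampled_meta_class_errors_with_name(self, rng):
        X, y = _separable_data(rng)
        y = np.where(y == 4, 3, y)
        y = np.where(y == 5, 3, y)  # "high" now has one observed member
        with pytest.raises(ValueError, match="high"):
            lh.HierarchicalClassifier(self.SPEC, "lr").fit(X, y)

    def test_schema_mismatch_raises(self, rng):
        X, y = _separable_data(rng)
        model = lh.HierarchicalClassifier(self.SPEC, "lr").fit(X, y)
        with pytest.raises(lh.SchemaError):
            model.predict(X[:, :5])

    @pytest.mark.parametrize("learner", ["lr", "knn", "gb", "svm"])
    def test_refit_determinism(self, learner, rng):
        X, y = _separable_data(rng, n_per_class=15, margin=1.5)
        kwargs = {"learner": lh.LearnerSpec(learner), "random_state": 7}
        a = lh.HierarchicalClassifier(self.SPEC, **kwargs).fit(X, y).predict(X)
        b = lh.HierarchicalClassifier(self.SPEC, **kwargs).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_mixed_best_task_learners(self, rng):
        X, y = _separable_data(rng)
        model = lh.HierarchicalClassifier(
            self.SPEC, "lr",
            task_learners={"high": lh.LearnerSpec("knn")},
        ).fit(X, y)
        assert type(model.sub_models["high"]).__name__ == "Pipeline"
        assert model.sub_models["high"].steps[-1][1].__class__.__name__ == (
            "KNeighborsClassifier"
        )

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = _separable_data(rng)
        model = lh.HierarchicalClassifier(self.SPEC, "lr").fit(X, y)
        model.save(tmp_path / "model.joblib")
        loaded = lh.HierarchicalClassifier.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            lh.LearnerSpec("random_forest")
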