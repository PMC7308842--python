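"""Two-level hierarchical classification.

A base learner assigns each window to a *meta-class* (a named group of
similar activities); a dedicated sub-learner per non-singleton meta-class
then resolves the final activity. Singleton meta-classes are terminal: the
base decision is the final label. A hierarchy where every meta-class is a
singleton therefore reduces exactly to flat multiclass classification.

The hierarchy is data, not code: any partition of the label set can be
supplied, including from a JSON/YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "MetaClass",
    "HierarchySpec",
    "LearnerSpec",
    "HierarchicalClassifier",
    "default_daliac_hierarchy",
    "DALIAC_ACTIVITIES",
    "DALIAC_CODES",
    "SchemaError",
]

#: The 13 DaLiAc daily-living activities, in their conventional code order
#: (codes 1..13).
DALIAC_ACTIVITIES = (
    "sit", "lie", "stand", "wash", "vacuum", "sweep", "walk",
    "stairs_up", "stairs_down", "run", "bike_50w", "bike_100w", "jump",
)
DALIAC_CODES: Mapping[str, int] = {a: i + 1 for i, a in enumerate(DALIAC_ACTIVITIES)}


class SchemaError(ValueError):
    """Prediction-time features do not match the training schema."""


@dataclass(frozen=True)
class MetaClass:
    """A named group of activity labels handled by one sub-classifier."""

    name: object
    members: tuple

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass(frozen=True)
class HierarchySpec:
    """An ordered partition of the activity labels into meta-classes."""

    meta_classes: tuple[MetaClass, ...]

    def __post_init__(self) -> None:
        seen: set = set()
        for mc in self.meta_classes:
            if not mc.members:
                raise ValueError(f"meta-class {mc.name!r} has no members")
            overlap = seen.intersection(mc.members)
            if overlap:
                raise ValueError(
                    f"labels {sorted(map(repr, overlap))} appear in more than "
                    "one meta-class; the hierarchy must be a partition"
                )
            seen.update(mc.members)

    @property
    def activities(self) -> tuple:
        return tuple(l for mc in self.meta_classes for l in mc.members)

    @property
    def non_singletons(self) -> tuple[MetaClass, ...]:
        return tuple(mc for mc in self.meta_classes if not mc.is_singleton)

    def meta_of(self, label):
        for mc in self.meta_classes:
            if label in mc.members:
                return mc.name
        raise KeyError(f"label {label!r} is not covered by the hierarchy")

    def meta_labels(self, labels: Sequence) -> np.ndarray:
        """Map activity labels to their meta-class names."""
        lut = {l: mc.name for mc in self.meta_classes for l in mc.members}
        try:
            return np.asarray([lut[l] for l in labels])
        except KeyError as exc:
            raise KeyError(
                f"label {exc.args[0]!r} is not covered by the hierarchy"
            ) from None

    @classmethod
    def flat(cls, labels: Sequence) -> "HierarchySpec":
        """Every label its own terminal meta-class (flat classification)."""
        uniq = sorted(set(labels), key=repr)
        try:
            uniq = sorted(set(labels))
        except TypeError:
            pass
        return cls(tuple(MetaClass(name=l, members=(l,)) for l in uniq))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [{"name": mc.name, "members": list(mc.members)}
                for mc in self.meta_classes]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "HierarchySpec":
        return cls(tuple(
            MetaClass(name=e["name"], members=tuple(e["members"]))
            for e in entries
        ))

    def save(self, path) -> None:
        import json

        import yaml

        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "HierarchySpec":
        import json

        import yaml

        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def default_daliac_hierarchy(use_codes: bool = False) -> HierarchySpec:
    """The 8-meta-class partition of the 13 DaLiAc activities.

    Four meta-classes group confusable activities and get a sub-classifier
    (stand/wash, vacuum/sweep, walk/stairs up/stairs down, the two cycling
    intensities); sitting, lying, running and rope jumping are terminal
    singletons.

    With ``use_codes=True`` members are the integer codes 1..13 instead of
    activity names.
    """
    groups = (
        ("sit", ("sit",)),
        ("lie", ("lie",)),
        ("stand_wash", ("stand", "wash")),
        ("vacuum_sweep", ("vacuum", "sweep")),
        ("walk_stairs", ("walk", "stairs_up", "stairs_down")),
        ("run", ("run",)),
        ("bike", ("bike_50w", "bike_100w")),
        ("jump", ("jump",)),
    )
    if use_codes:
        groups = tuple(
            (name, tuple(DALIAC_CODES[m] for m in members))
            for name, members in groups
        )
    return HierarchySpec(tuple(MetaClass(n, m) for n, m in groups))


# -- learners ----------------------------------------------------------------

_LEARNER_ALIASES = {
    "lr": "logistic_regression", "logistic_regression": "logistic_regression",
    "knn": "knn",
    "gb": "gradient_boosting", "gradient_boosting": "gradient_boosting",
    "svm": "svm",
}


@dataclass(frozen=True)
class LearnerSpec:
    """A named base learner with its (few) fixed hyperparameters.

    Defaults: logistic regression with L2 regularization and penalty
    coefficient C = 1; KNN with k = 5; gradient boosting with 500 estimators
    considering 10 features per split; SVM at library defaults.
    """

    name: str = "logistic_regression"
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _LEARNER_ALIASES:
            raise ValueError(
                f"unknown learner {self.name!r}; choose from "
                f"{sorted(set(_LEARNER_ALIASES))}"
            )
        object.__setattr__(self, "name", _LEARNER_ALIASES[self.name])

    def make(self, random_state: int | None = 0, n_features: int | None = None):
        """Instantiate the scikit-learn estimator behind this spec.

        Scale-sensitive learners (LR with L2 penalty, KNN, SVM) are wrapped
        in a feature standardizer fitted on their own training rows; the
        feature columns span several orders of magnitude (e.g. spectral
        energy vs. percentiles of z-scored signals) and would otherwise
        dominate the penalty / the distance metric.
        """
        p = dict(self.params)
        scale = p.pop("scale_features", self.name != "gradient_boosting")
        if self.name == "logistic_regression":
            p.setdefault("C", 1.0)  # L2 regularization, penalty coefficient 1
            p.setdefault("max_iter", 1000)
            est = LogisticRegression(random_state=random_state, **p)
        elif self.name == "knn":
            p.setdefault("n_neighbors", 5)
            est = KNeighborsClassifier(**p)
        elif self.name == "gradient_boosting":
            p.setdefault("n_estimators", 500)
            max_features = p.pop("max_features", 10)
            if n_features is not None and isinstance(max_features, int):
                max_features = min(max_features, n_features)
            est = GradientBoostingClassifier(
                max_features=max_features, random_state=random_state, **p
            )
        else:
            est = SVC(random_state=random_state, **p)
        if scale:
            return make_pipeline(StandardScaler(), est)
        return est


class HierarchicalClassifier:
    """Base learner over meta-classes + one sub-learner per non-singleton
    meta-class.

    Sub-learners are trained on the rows whose *true* meta-class matches
    (standard hierarchical training). ``task_learners`` optionally assigns a
    different ``LearnerSpec`` per task name (``"base"`` or a meta-class
    name), enabling mixed-best systems.
    """

    def __init__(self, spec: HierarchySpec,
                 learner: LearnerSpec | str = LearnerSpec(),
                 task_learners: Mapping[object, LearnerSpec] | None = None,
                 random_state: int = 0):
        self.spec = spec
        self.learner = LearnerSpec(learner) if isinstance(learner, str) else learner
        self.task_learners = dict(task_learners or {})
        self.random_state = random_state
        self.base_model = None
        self.sub_models: dict = {}
        self.n_features_in_: int | None = None

    def _learner_for(self, task) -> LearnerSpec:
        return self.task_learners.get(task, self.learner)

    def fit(self, X, y) -> "HierarchicalClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.n_features_in_ = X.shape[1]
        self._label_example = y[:1]

        y_meta = self.spec.meta_labels(y)
        if np.unique(y_meta).size < 2:
            raise ValueError("need at least 2 meta-classes present to train")
        self.base_model = self._learner_for("base").make(
            self.random_state, X.shape[1]
        )
        self.base_model.fit(X, y_meta)

        self.sub_models = {}
        for mc in self.spec.non_singletons:
            mask = y_meta == mc.name
            members_seen = np.unique(y[mask])
            if members_seen.size < 2:
                raise ValueError(
                    f"meta-class {mc.name!r} needs >= 2 observed member "
                    f"classes to train a sub-classifier, found "
                    f"{members_seen.tolist()}"
                )
            sub = self._learner_for(mc.name).make(self.random_state, X.shape[1])
            sub.fit(X[mask], y[mask])
            self.sub_models[mc.name] = sub
        return self

    def _check_schema(self, X) -> np.ndarray:
        if self.base_model is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} feature columns, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        return X

    def predict_meta(self, X) -> np.ndarray:
        """Base-level meta-class assignment for each row."""
        return np.asarray(self.base_model.predict(self._check_schema(X)))

    def predict(self, X) -> np.ndarray:
        """Final activity labels; each one belongs to its predicted
        meta-class by construction."""
        X = self._check_schema(X)
        meta = np.asarray(self.base_model.predict(X))
        out = np.empty(X.shape[0], dtype=object)
        by_name = {mc.name: mc for mc in self.spec.meta_classes}
        for name in np.unique(meta):
            mask = meta == name
            mc = by_name[name]
            if mc.is_singleton:
                out[mask] = mc.members[0]
            else:
                out[mask] = self.sub_models[name].predict(X[mask])
        try:
            return out.astype(self._label_example.dtype)
        except (TypeError, ValueError):
            return out

    def save(self, path) -> None:
        """Persist the fitted model (base + sub-models + schema) to one file."""
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "HierarchicalClassifier":
        return joblib.load(path)
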