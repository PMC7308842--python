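"""Leave-one-subject-out (LOSO) evaluation, per-class metrics, and the
device-combination / gyroscope-ablation sweeps.

LOSO trains on all subjects but one and tests on the held-out subject, once
per subject. Because activity patterns are subject-specific, holding out
windows instead of subjects inflates accuracy; LOSO is the honest protocol
for body-worn sensor classifiers. Per-class precision/recall/f-score are
computed from the confusion matrix aggregated over all rounds.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .feature_extraction import FeatureMatrix, build_feature_matrix
from .hierarchy import HierarchicalClassifier, HierarchySpec, LearnerSpec
from .signal_pipeline import PipelineConfig, preprocess
from .types import SensorRecording

__all__ = [
    "ConfusionMatrix",
    "LosoResult",
    "loso_split",
    "confusion_metrics",
    "run_loso",
    "loso_from_features",
    "combination_sweep",
    "device_subsets",
]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K matching the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        if classes is None:
            classes = sorted(set(np.asarray(y_true).tolist())
                             | set(np.asarray(y_pred).tolist()))
        counts = _sk_confusion(y_true, y_pred, labels=list(classes))
        return cls(counts=counts, classes=list(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, list(self.classes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def confusion_metrics(m: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision, recall and f-score (beta = 1).

    precision_k = m[k,k] / column-sum_k, recall_k = m[k,k] / row-sum_k,
    f_k = 2 p r / (p + r). A zero denominator yields 0 with a warning.
    Values are kept at full precision; round for display.
    """
    counts = m.counts.astype(float)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    if (col == 0).any() or (row == 0).any():
        warnings.warn("confusion matrix has empty row(s)/column(s); the "
                      "affected metrics are reported as 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return pd.DataFrame(
        {"precision": precision, "recall": recall, "f_score": f},
        index=m.classes,
    )


def loso_split(subject_ids: Sequence) -> list[tuple[list, object]]:
    """One fold per distinct subject: (train subjects, held-out subject)."""
    subjects = list(dict.fromkeys(subject_ids))  # unique, first-appearance order
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [
        ([s for s in subjects if s != test], test)
        for test in subjects
    ]


@dataclass
class LosoResult:
    """Summary of one LOSO evaluation."""

    fold_subjects: list
    fold_accuracies: list[float]
    confusion: ConfusionMatrix
    per_class: pd.DataFrame
    subtask_accuracies: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        # population sd across folds
        return float(np.std(self.fold_accuracies))

    def summary(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "n_folds": len(self.fold_accuracies),
            "n_windows": self.confusion.total,
            "fold_subjects": [str(s) for s in self.fold_subjects],
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "subtask_accuracies": {
                str(k): {kk: float(vv) for kk, vv in v.items()}
                for k, v in self.subtask_accuracies.items()
            },
            "config": self.config,
        }

    def save(self, out_dir) -> None:
        """Write JSON summary, confusion-matrix CSV and per-class CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(self.summary(), indent=2))
        self.confusion.to_csv(out / "confusion_matrix.csv")
        self.per_class.to_csv(out / "per_class_metrics.csv")


def loso_from_features(features: FeatureMatrix, spec: HierarchySpec,
                       learner: LearnerSpec | str = LearnerSpec(),
                       task_learners: Mapping | None = None,
                       seed: int = 0,
                       oracle_routing: bool = False) -> LosoResult:
    """LOSO over a prebuilt feature matrix (rows grouped by subject)."""
    classes = sorted(set(features.labels.tolist()))
    folds = loso_split(features.subject_ids)

    fold_acc: list[float] = []
    fold_subjects: list = []
    agg: ConfusionMatrix | None = None
    subtasks: dict[object, list[float]] = {"base": []}
    for mc in spec.non_singletons:
        subtasks[mc.name] = []

    for train_subjects, test_subject in folds:
        train_mask = np.isin(features.subject_ids, train_subjects)
        test_mask = features.subject_ids == test_subject
        model = HierarchicalClassifier(
            spec, learner, task_learners, random_state=seed
        )
        model.fit(features.X[train_mask], features.labels[train_mask])
        y_true = features.labels[test_mask]
        y_pred = model.predict(features.X[test_mask])

        fold_subjects.append(test_subject)
        fold_acc.append(float(np.mean(y_pred == y_true)))
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, classes)
        agg = cm if agg is None else agg + cm

        # base task: score meta-class assignment
        meta_true = spec.meta_labels(y_true)
        meta_pred = model.predict_meta(features.X[test_mask])
        subtasks["base"].append(float(np.mean(meta_pred == meta_true)))
        # sub-tasks: restrict to rows whose true class is in the meta-class
        for mc in spec.non_singletons:
            mask = np.isin(y_true, mc.members)
            if not mask.any():
                subtasks[mc.name].append(np.nan)
                continue
            if oracle_routing:
                pred = model.sub_models[mc.name].predict(
                    features.X[test_mask][mask]
                )
            else:
                pred = y_pred[mask]
            subtasks[mc.name].append(float(np.mean(pred == y_true[mask])))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        subtask_summary = {
            name: {"mean": float(np.nanmean(vals)),
                   "sd": float(np.nanstd(vals))}
            for name, vals in subtasks.items()
        }
    return LosoResult(
        fold_subjects=fold_subjects,
        fold_accuracies=fold_acc,
        confusion=agg,
        per_class=confusion_metrics(agg),
        subtask_accuracies=subtask_summary,
        config=dict(features.config, seed=seed,
                    learner=getattr(learner, "name", str(learner))),
    )


def run_loso(recordings: Sequence[SensorRecording], spec: HierarchySpec,
             learner: LearnerSpec | str = LearnerSpec(),
             devices: Sequence[str] | None = None,
             include_gyro: bool = True, include_mag: bool = False,
             config: PipelineConfig = PipelineConfig(),
             task_learners: Mapping | None = None,
             seed: int = 0, oracle_routing: bool = False) -> LosoResult:
    """Full pipeline LOSO: preprocess -> features -> fit/predict per fold.

    Preprocessing (decomposition, decimation, per-recording normalization)
    is strictly per recording, so no statistic of a held-out subject ever
    reaches a training fold.
    """
    bundles = [preprocess(r, config) for r in recordings]
    features = build_feature_matrix(
        bundles, devices=devices, include_gyro=include_gyro,
        include_mag=include_mag, config=config,
    )
    return loso_from_features(
        features, spec, learner, task_learners, seed, oracle_routing
    )


def device_subsets(locations: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    locations = sorted(set(locations))
    out: list[tuple[str, ...]] = []
    for size in range(1, len(locations) + 1):
        out.extend(itertools.combinations(locations, size))
    return out


def combination_sweep(recordings: Sequence[SensorRecording],
                      spec: HierarchySpec,
                      learner: LearnerSpec | str = LearnerSpec(),
                      config: PipelineConfig = PipelineConfig(),
                      locations: Sequence[str] | None = None,
                      include_mag: bool = False,
                      seed: int = 0) -> pd.DataFrame:
    """LOSO accuracy for every device subset, with and without gyroscopes.

    Four locations yield 15 subsets x 2 gyro settings = 30 rows. Features
    are extracted once over all channels and sliced per subset.
    """
    bundles = [preprocess(r, config) for r in recordings]
    if locations is None:
        locations = sorted({b.device_location for b in bundles})
    full = build_feature_matrix(
        bundles, devices=sorted(set(locations)), include_gyro=True,
        include_mag=include_mag, config=config,
    )
    rows = []
    for subset in device_subsets(locations):
        for gyro in (True, False):
            fm = full.select(devices=subset, include_gyro=gyro,
                             include_mag=include_mag)
            res = loso_from_features(fm, spec, learner, seed=seed)
            rows.append({
                "devices": "|".join(subset),
                "n_devices": len(subset),
                "gyro": gyro,
                "mean_accuracy": res.mean_accuracy,
                "sd_accuracy": res.sd_accuracy,
                "n_windows": res.confusion.total,
            })
    return pd.DataFrame(rows)
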