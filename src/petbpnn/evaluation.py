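"""Hold-out evaluation protocol for binary NC-vs-disease experiments.

A single stratified random split assigns 30% of each class to training and
the remaining 70% to testing (no cross-validation).  Each binary experiment
trains an independent network and reports a confusion matrix with the
*disease* group as the positive class and NC as the negative class, plus
sensitivity, specificity and accuracy in percent, rounded half away from
zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bpnn import NetworkConfig, TrainResult, predict, train
from .exceptions import UndefinedMetricError, ValidationError
from .image_io import CLASS_LABELS, Manifest

__all__ = [
    "SplitPlan",
    "ConfusionCounts",
    "EvaluationReport",
    "LabeledDataset",
    "ExperimentResult",
    "make_split",
    "compute_metrics",
    "run_experiment",
]


@dataclass
class LabeledDataset:
    """Feature vectors with class labels, indexed by source_id."""

    ids: list[str]
    labels: list[str]
    X: np.ndarray  # (n_samples, n_features)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if not (len(self.ids) == len(self.labels) == self.X.shape[0]):
            raise ValidationError("ids, labels and X row count must agree")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabeledDataset":
        feat_cols = [c for c in df.columns if c.startswith("f")]
        return cls(
            ids=df["source_id"].astype(str).tolist(),
            labels=df["label"].astype(str).tolist(),
            X=df[feat_cols].to_numpy(dtype=np.float64),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        return cls.from_dataframe(pd.read_csv(path))

    def subset(self, ids: Sequence[str]) -> "LabeledDataset":
        index = {sid: i for i, sid in enumerate(self.ids)}
        rows = [index[sid] for sid in ids]
        return LabeledDataset(
            ids=[self.ids[i] for i in rows],
            labels=[self.labels[i] for i in rows],
            X=self.X[rows],
        )


@dataclass
class SplitPlan:
    """Disjoint per-class train/test id sets from a stratified random split."""

    train_ids: dict[str, list[str]]
    test_ids: dict[str, list[str]]
    train_fraction: float
    seed: int

    def all_train(self) -> list[str]:
        return [sid for ids in self.train_ids.values() for sid in ids]

    def all_test(self) -> list[str]:
        return [sid for ids in self.test_ids.values() for sid in ids]


@dataclass
class ConfusionCounts:
    """tp/fn count disease-group test cases; tn/fp count NC test cases."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass
class EvaluationReport:
    experiment: str
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "positive_class": "disease group",
            "negative_class": "NC",
            "counts": vars(self.counts).copy(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _round1(x: float) -> float:
    """Round half away from zero to one decimal."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


def make_split(
    manifest: Manifest,
    classes: tuple[str, str],
    train_fraction: float = 0.30,
    seed: int = 0,
) -> SplitPlan:
    """Seeded stratified split: per class, round(train_fraction * n) ids train."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: dict[str, list[str]] = {}
    test_ids: dict[str, list[str]] = {}
    for label in classes:
        ids = manifest.ids_for(label)
        if len(ids) < 2:
            raise ValidationError(
                f"class {label!r} has {len(ids)} images; need at least 2"
            )
        order = rng.permutation(len(ids))
        n_train = int(math.floor(train_fraction * len(ids) + 0.5))
        shuffled = [ids[i] for i in order]
        train_ids[label] = sorted(shuffled[:n_train])
        test_ids[label] = sorted(shuffled[n_train:])
    return SplitPlan(train_ids, test_ids, train_fraction, seed)


def compute_metrics(counts: ConfusionCounts, experiment: str = "") -> EvaluationReport:
    """Sensitivity, specificity and accuracy (percent, one decimal) from counts."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        raise UndefinedMetricError(
            f"need at least one positive and one negative test case "
            f"(tp+fn={pos}, tn+fp={neg})"
        )
    total = pos + neg
    return EvaluationReport(
        experiment=experiment,
        counts=counts,
        sensitivity=_round1(100.0 * counts.tp / pos),
        specificity=_round1(100.0 * counts.tn / neg),
        accuracy=_round1(100.0 * (counts.tp + counts.tn) / total),
    )


@dataclass
class ExperimentResult:
    report: EvaluationReport
    train_result: TrainResult
    train_accuracy: float  # percent on the training patterns themselves
    split: SplitPlan


def _as_manifest(dataset: LabeledDataset) -> Manifest:
    from .image_io import ManifestEntry

    return Manifest(
        [ManifestEntry(sid, "", lab) for sid, lab in zip(dataset.ids, dataset.labels)]
    )


def run_experiment(
    features: LabeledDataset,
    classes: tuple[str, str],
    cfg: NetworkConfig,
    split_seed: int = 0,
) -> ExperimentResult:
    """Split, train an independent network, score the held-out 70%.

    ``classes`` is ``(negative_label, positive_label)`` — by protocol
    ``("NC", <disease>)``.  Output neuron 0 encodes the negative class and
    neuron 1 the positive (disease) class.
    """
    neg_label, pos_label = classes
    for label in classes:
        if label not in CLASS_LABELS:
            raise ValidationError(f"unknown class label {label!r}")
        if label not in features.labels:
            raise ValidationError(f"dataset contains no {label!r} samples")
    split = make_split(_as_manifest(features), classes, seed=split_seed)

    class_index = {neg_label: 0, pos_label: 1}
    train_set = features.subset(split.all_train())
    test_set = features.subset(split.all_test())
    patterns = [
        (x, class_index[lab]) for x, lab in zip(train_set.X, train_set.labels)
    ]
    result = train(patterns, cfg)

    train_pred = [predict(result.state, x) for x in train_set.X]
    train_true = [class_index[lab] for lab in train_set.labels]
    train_acc = 100.0 * float(np.mean(np.array(train_pred) == np.array(train_true)))

    tp = tn = fp = fn = 0
    for x, lab in zip(test_set.X, test_set.labels):
        pred = predict(result.state, x)
        if lab == pos_label:
            if pred == 1:
                tp += 1
            else:
                fn += 1
        else:
            if pred == 0:
                tn += 1
            else:
                fp += 1
    report = compute_metrics(
        ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn),
        experiment=f"{neg_label}/{pos_label}",
    )
    return ExperimentResult(
        report=report,
        train_result=result,
        train_accuracy=train_acc,
        split=split,
    )
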