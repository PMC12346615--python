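"""Cross-validation protocol and confusion-matrix metrics.

Patients are split with stratified, patient-level k-fold cross-validation:
within each class, patients are shuffled once from the seed and dealt
round-robin into k test folds, so fold class counts differ from
proportional by at most one; the remaining patients of each fold are then
split train/validation, again stratified by class.  Fold metrics are
aggregated as mean ± sample standard deviation.

AUC is the rank statistic (probability that a random positive outranks a
random negative, ties counted 1/2); the remaining metrics come from the
confusion matrix at a fixed threshold.  Ratios with a zero denominator
are reported as 0 and flagged undefined rather than raised, which keeps
fold aggregation total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import ValidationError
from .io import FeatureBag
from .model import MilModelParams, TrainConfig, TrainResult, predict_bag, train_model

METRIC_NAMES = ("accuracy", "auc", "f1", "sensitivity", "specificity", "precision")


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def assert_disjoint(self) -> None:
        train, val, test = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if train & val or train & test or val & test:
            raise ValidationError(f"fold {self.fold_index}: train/val/test sets overlap")


def stratified_kfold_split(
    patient_ids: Sequence[str],
    labels: Sequence[int],
    k: int = 5,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> list[FoldSplit]:
    """Stratified patient-level k-fold splits, deterministic in ``seed``.

    Per class: shuffle, deal round-robin into k test folds.  Within each
    fold the non-test patients are split train/val per class at
    ``val_fraction`` (at least one validation patient per class).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    patient_ids = [str(p) for p in patient_ids]
    labels = np.asarray(labels, dtype=int)
    if len(patient_ids) != len(labels):
        raise ValidationError("patient_ids and labels must have equal length")

    root = np.random.SeedSequence(seed)
    deal_seq, *fold_seqs = root.spawn(k + 1)
    deal_rng = np.random.default_rng(deal_seq)

    test_folds: list[list[str]] = [[] for _ in range(k)]
    by_class: dict[int, list[str]] = {}
    for cls in (0, 1):
        members = [p for p, l in zip(patient_ids, labels) if l == cls]
        if len(members) < k:
            raise ValidationError(f"class {cls} has {len(members)} patients, fewer than k={k}")
        members = [members[i] for i in deal_rng.permutation(len(members))]
        by_class[cls] = members
        for i, pid in enumerate(members):
            test_folds[i % k].append(pid)

    label_of = dict(zip(patient_ids, (int(l) for l in labels)))
    splits = []
    for f in range(k):
        test = sorted(test_folds[f])
        rest = [p for p in patient_ids if p not in set(test)]
        fold_rng = np.random.default_rng(fold_seqs[f])
        train: list[str] = []
        val: list[str] = []
        for cls in (0, 1):
            members = [p for p in rest if label_of[p] == cls]
            members = [members[i] for i in fold_rng.permutation(len(members))]
            n_val = max(1, int(round(val_fraction * len(members))))
            val.extend(members[:n_val])
            train.extend(members[n_val:])
        split = FoldSplit(fold_index=f + 1, train_ids=sorted(train), val_ids=sorted(val), test_ids=test)
        split.assert_disjoint()
        splits.append(split)
    return splits


def confusion_counts(
    y_true: Sequence[int], y_score: Sequence[float], threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) at the given threshold; predicted positive iff
    score >= threshold."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.size == 0:
        raise ValidationError("cannot compute a confusion matrix on empty input")
    if y_true.shape != y_score.shape:
        raise ValidationError("y_true and y_score must have equal length")
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    pred = (y_score >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics for one evaluation.

    ``undefined`` lists metrics whose denominator was zero (reported as 0).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    auc: float
    f1: float
    sensitivity: float
    specificity: float
    precision: float
    threshold: float
    undefined: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _safe_ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(
    y_true: Sequence[int], y_score: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Accuracy / precision / recall (sensitivity) / specificity / F1 from
    the confusion matrix, plus rank-based AUC."""
    tp, fp, fn, tn = confusion_counts(y_true, y_score, threshold)
    undefined: list[str] = []
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n
    precision = _safe_ratio(tp, tp + fp, "precision", undefined)
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", undefined)
    specificity = _safe_ratio(tn, tn + fp, "specificity", undefined)
    f1 = _safe_ratio(2 * precision * sensitivity, precision + sensitivity, "f1", undefined)
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        undefined.append("auc")
        auc = 0.0
    else:
        auc = float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))
    return MetricsReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, auc=auc, f1=f1,
        sensitivity=sensitivity, specificity=specificity, precision=precision,
        threshold=threshold, undefined=undefined,
    )


def roc_points(y_true: Sequence[int], y_score: Sequence[float]) -> np.ndarray:
    """ROC curve as an array of (fpr, tpr, threshold) rows."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true, dtype=int), np.asarray(y_score, dtype=float))
    return np.column_stack([fpr, tpr, thr])


@dataclass
class CrossValReport:
    folds: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]
    mean_2dp: dict[str, float]
    std_2dp: dict[str, float]


def aggregate_folds(reports: Sequence[MetricsReport]) -> CrossValReport:
    """Mean and sample (n-1) standard deviation per metric across folds;
    std is 0 for a single fold.  Two-decimal roundings are exposed for
    report rendering."""
    if not reports:
        raise ValidationError("need at least one fold report")
    mean, std = {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        mean[m] = float(vals.mean())
        std[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CrossValReport(
        folds=list(reports),
        mean=mean,
        std=std,
        mean_2dp={m: round(v, 2) for m, v in mean.items()},
        std_2dp={m: round(v, 2) for m, v in std.items()},
    )


@dataclass
class FoldOutcome:
    split: FoldSplit
    result: TrainResult
    test_ids: list[str]
    y_true: np.ndarray
    y_score: np.ndarray
    metrics: MetricsReport
    roc: np.ndarray


def run_cross_validation(
    bags: Sequence[FeatureBag],
    cfg: TrainConfig,
    k: int = 5,
    val_fraction: float = 0.1,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[CrossValReport, list[FoldOutcome]]:
    """Full stratified k-fold protocol: per fold, train on train/val and
    score the held-out test patients at ``threshold``.

    Per-fold training seeds derive from ``cfg.seed + fold_index`` so folds
    are independent and the whole run is reproducible.  Disjointness of
    every fold's train/val/test patient sets is asserted (leakage guard).
    """
    by_pid = {b.patient_id: b for b in bags}
    if len(by_pid) != len(bags):
        raise ValidationError("duplicate patient_id among bags")
    if any(b.label is None for b in bags):
        raise ValidationError("all bags must be labeled for cross-validation")
    ids = [b.patient_id for b in bags]
    labels = [int(b.label) for b in bags]

    splits = stratified_kfold_split(ids, labels, k=k, val_fraction=val_fraction, seed=seed)
    covered = sorted(pid for s in splits for pid in s.test_ids)
    if covered != sorted(ids):
        raise ValidationError("test folds do not partition the cohort")

    outcomes = []
    for split in splits:
        split.assert_disjoint()
        fold_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, weight_decay=cfg.weight_decay,
            max_epochs=cfg.max_epochs, patience=cfg.patience, L=cfg.L,
            seed=cfg.seed + split.fold_index, jitter_magnitude=cfg.jitter_magnitude,
        )
        result = train_model(
            [by_pid[p] for p in split.train_ids],
            [by_pid[p] for p in split.val_ids],
            fold_cfg,
        )
        y_true = np.array([by_pid[p].label for p in split.test_ids], dtype=int)
        y_score = np.array([predict_bag(by_pid[p], result.params) for p in split.test_ids])
        metrics = compute_metrics(y_true, y_score, threshold)
        outcomes.append(
            FoldOutcome(
                split=split, result=result, test_ids=split.test_ids,
                y_true=y_true, y_score=y_score, metrics=metrics,
                roc=roc_points(y_true, y_score),
            )
        )
    report = aggregate_folds([o.metrics for o in outcomes])
    return report, outcomes


def evaluate_external(
    models: Sequence[MilModelParams],
    bags: Sequence[FeatureBag],
    threshold: float = 0.5,
) -> CrossValReport:
    """Score a labeled external cohort with each trained model and report
    per-model metrics plus mean ± std across the models, which play the
    role of independent runs."""
    if not models:
        raise ValidationError("need at least one model")
    if any(b.label is None for b in bags):
        raise ValidationError("external cohort must be labeled")
    dims = {m.d for m in models} | {b.dim for b in bags}
    if len(dims) != 1:
        raise ValidationError(f"model/cohort dimension mismatch: {sorted(dims)}")
    y_true = np.array([b.label for b in bags], dtype=int)
    reports = []
    for m in models:
        y_score = np.array([predict_bag(b, m) for b in bags])
        reports.append(compute_metrics(y_true, y_score, threshold))
    return aggregate_folds(reports)
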