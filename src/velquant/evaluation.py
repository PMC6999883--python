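"""Multiclass evaluation: splits, confusion tables, metrics and ROC.

Confusion tables are oriented rows = actual class, columns = predicted
class.  Per-class metrics come from the one-vs-rest decomposition

    precision = TP / (TP + FP),   recall = TP / (TP + FN),
    F1 = 2 * precision * recall / (precision + recall),

with TP the diagonal entry, FN the rest of the row, FP the rest of the
column, and multiclass accuracy = trace / total.  A zero denominator
yields 0 with an ``undefined`` flag.  ROC curves are one-vs-rest
threshold sweeps over a positive-class score, with ties grouped so each
distinct score contributes one step; the macro-average curve interpolates
every per-class curve onto a common false-positive-rate grid and averages
the true-positive rates pointwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def stratified_split(
    dataset: pd.DataFrame,
    train_fraction: float,
    seed: int,
    label_col: str = "label",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Class-stratified train/test split.

    Each class contributes ``floor(train_fraction * n_c)`` training rows
    (so e.g. 150 tongue samples of sizes 55/55/40 at 0.75 give 112 train
    and 38 test).  Deterministic per seed; raises if any class would be
    missing from either side.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts: List[pd.DataFrame] = []
    test_parts: List[pd.DataFrame] = []
    for cls_label, group in dataset.groupby(label_col, sort=True):
        n = len(group)
        n_train = int(np.floor(train_fraction * n))
        if n_train < 1 or n_train >= n:
            raise ValueError(
                f"class {cls_label!r} with {n} samples cannot appear in both "
                f"partitions at fraction {train_fraction}"
            )
        perm = rng.permutation(n)
        train_parts.append(group.iloc[perm[:n_train]])
        test_parts.append(group.iloc[perm[n_train:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def kfold_indices(
    dataset: pd.DataFrame,
    k: int,
    seed: int,
    label_col: str = "label",
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold positional indices.

    Returns k (train_idx, test_idx) pairs; every sample appears in
    exactly one test fold and the folds are near-equal in size per class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    labels = dataset[label_col].to_numpy()
    fold_members: List[List[int]] = [[] for _ in range(k)]
    for cls_label in sorted(pd.unique(labels).tolist()):
        pos = np.flatnonzero(labels == cls_label)
        if len(pos) < k:
            raise ValueError(
                f"class {cls_label!r} has {len(pos)} samples, fewer than k={k}"
            )
        perm = rng.permutation(len(pos))
        for fold, chunk in enumerate(np.array_split(pos[perm], k)):
            fold_members[fold].extend(chunk.tolist())
    out = []
    all_idx = np.arange(len(dataset))
    for fold in range(k):
        test_idx = np.sort(np.array(fold_members[fold], dtype=int))
        train_idx = np.setdiff1d(all_idx, test_idx)
        out.append((train_idx, test_idx))
    return out


# ---------------------------------------------------------------------------
# Confusion tables and metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """Square count table, rows = actual class, columns = predicted."""

    classes: Tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        K = len(self.classes)
        if counts.shape != (K, K):
            raise ValueError(f"counts must be {K}x{K}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """Per-class actual supports (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.classes), columns=list(self.classes)
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("# rows=actual, columns=predicted\n")
            self.to_dataframe().to_csv(fh, index_label="actual")

    def permuted(self, order: Sequence[str]) -> "ConfusionTable":
        idx = [self.classes.index(c) for c in order]
        return ConfusionTable(tuple(order), self.counts[np.ix_(idx, idx)])


def confusion_table(
    actual: Sequence[str],
    predicted: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionTable:
    """Tally counts[i][j] = #(actual == class_i and predicted == class_j)."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    classes = tuple(class_order)
    index = {c: i for i, c in enumerate(classes)}
    K = len(classes)
    counts = np.zeros((K, K), dtype=int)
    for a, p in zip(actual.tolist(), predicted.tolist()):
        if a not in index or p not in index:
            raise ValueError(f"unknown label in pair ({a!r}, {p!r})")
        counts[index[a], index[p]] += 1
    return ConfusionTable(classes, counts)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest counts and derived metrics for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 plus accuracy and averages.

    ``macro_*`` are unweighted means over classes; ``weighted_*`` are
    support-weighted (under which weighted recall equals accuracy).
    """

    classes: Tuple[str, ...]
    per_class: Dict[str, ClassMetrics]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    total: int

    def to_dict(self) -> Dict:
        return {
            "classes": list(self.classes),
            "accuracy": self.accuracy,
            "total": self.total,
            "per_class": {
                c: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "tn": m.tn,
                    "precision_defined": m.precision_defined,
                    "recall_defined": m.recall_defined,
                }
                for c, m in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def metrics_from_confusion(table: ConfusionTable) -> MetricsReport:
    """Compute the full multiclass metric report from a confusion table."""
    total = table.total
    if total < 1:
        raise ValueError("confusion table is empty")
    counts = table.counts
    per_class: Dict[str, ClassMetrics] = {}
    precs, recs, f1s = [], [], []
    supports = table.supports
    for i, cls_label in enumerate(table.classes):
        tp = int(counts[i, i])
        fn = int(counts[i, :].sum() - tp)
        fp = int(counts[:, i].sum() - tp)
        tn = total - tp - fn - fp
        p_def = (tp + fp) > 0
        r_def = (tp + fn) > 0
        precision = tp / (tp + fp) if p_def else 0.0
        recall = tp / (tp + fn) if r_def else 0.0
        f1 = (
            2.0 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[cls_label] = ClassMetrics(
            tp, fp, fn, tn, precision, recall, f1, p_def, r_def
        )
        precs.append(precision)
        recs.append(recall)
        f1s.append(f1)
    precs_a, recs_a, f1s_a = map(np.asarray, (precs, recs, f1s))
    w = supports / total
    return MetricsReport(
        classes=table.classes,
        per_class=per_class,
        accuracy=float(np.trace(counts)) / total,
        macro_precision=float(precs_a.mean()),
        macro_recall=float(recs_a.mean()),
        macro_f1=float(f1s_a.mean()),
        weighted_precision=float(precs_a @ w),
        weighted_recall=float(recs_a @ w),
        weighted_f1=float(f1s_a @ w),
        total=total,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """One-vs-rest (or macro-average) ROC polyline with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    label: str
    mode: Optional[str] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_ovr(
    actual: Sequence[str],
    posteriors: np.ndarray,
    positive_class: str,
    class_order: Optional[Sequence[str]] = None,
    mode: Optional[str] = None,
) -> ROCCurve:
    """One-vs-rest ROC for ``positive_class``.

    ``posteriors`` is either an (n, K) probability matrix (then
    ``class_order`` selects the positive column) or a 1-D score array.
    Tied scores are grouped so each distinct score is a single operating
    point; the curve is anchored at (0, 0) and (1, 1) and the AUC is the
    trapezoidal integral (equal to the tie-corrected Mann-Whitney
    statistic divided by n_pos * n_neg).
    """
    actual = np.asarray(actual)
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.ndim == 2:
        if class_order is None:
            raise ValueError("class_order is required for 2-D posteriors")
        scores = posteriors[:, list(class_order).index(positive_class)]
    else:
        scores = posteriors
    if scores.shape[0] != actual.shape[0]:
        raise ValueError("scores and actual length mismatch")
    y = actual == positive_class
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"ROC needs both positive and negative samples for {positive_class!r}"
        )
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    keep = np.r_[distinct, s_sorted.size - 1]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, label=positive_class, mode=mode)


def macro_average_roc(curves: Sequence[ROCCurve], n_grid: int = 101) -> ROCCurve:
    """Average per-class ROC curves on a common FPR grid.

    Each curve's TPR is linearly interpolated onto ``n_grid`` evenly
    spaced FPR values in [0, 1] (duplicate FPRs collapse to their maximum
    TPR), the TPRs are averaged pointwise, and the AUC of the averaged
    polyline is reported.
    """
    if not curves:
        raise ValueError("at least one curve is required")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for curve in curves:
        fpr = np.asarray(curve.fpr, dtype=float)
        tpr = np.asarray(curve.tpr, dtype=float)
        # collapse duplicate FPR values to the max TPR reached there
        uniq, inverse = np.unique(fpr, return_inverse=True)
        best = np.zeros_like(uniq)
        np.maximum.at(best, inverse, tpr)
        tprs.append(np.interp(grid, uniq, best))
    mean_tpr = np.mean(tprs, axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    modes = {c.mode for c in curves}
    return ROCCurve(
        fpr=grid, tpr=mean_tpr, auc=auc, label="macro",
        mode=modes.pop() if len(modes) == 1 else None,
    )
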