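"""Performance metrics: accuracy, macro F1, ROC AUC, confusion matrices.

Multiclass ROC AUC is the unweighted (macro) mean of one-vs-rest AUCs; the
per-class F1 uses the 2TP / (2TP + FP + FN) form with the 0/0 convention
F1 = 0.  Confusion matrices can be row-normalized and rounded for display,
and the four-muscle matrix can be aggregated to a 2x2 upper/lower-extremity
matrix by summing within-limb cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .learning import Algorithm, Paradigm, Predictions, Representation
from .synthetic import Extremity, MuscleClass

logger = logging.getLogger(__name__)


def accuracy(preds: Sequence, labels: Sequence) -> float:
    """Fraction of correct classifications."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.size == 0 or preds.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(_skm.accuracy_score(labels, preds))


def f1_macro(preds: Sequence, labels: Sequence) -> float:
    """Unweighted mean over classes of one-vs-rest F1 = 2TP/(2TP+FP+FN).

    A class with no true and no predicted members contributes 0.
    """
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.size == 0 or preds.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(_skm.f1_score(labels, preds, average="macro", zero_division=0))


def roc_auc(scores: np.ndarray, labels: Sequence,
            classes: Sequence[str]) -> float:
    """Rank-based ROC AUC (ties count half).

    Binary problems use the positive-class score column directly; multiclass
    problems take the macro mean of one-vs-rest AUCs over the classes present
    in ``labels`` (absent classes are skipped with a warning).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = list(classes)
    present = [c for c in classes if np.any(labels == c)]
    if len(present) < 2:
        raise ValueError("ROC AUC needs at least 2 classes present")
    if len(classes) == 2:
        pos = classes[1]
        return float(_skm.roc_auc_score(labels == pos, scores[:, 1]))
    aucs = []
    for j, c in enumerate(classes):
        if c not in present:
            logger.warning("ROC AUC: class %s absent from labels, skipped", c)
            continue
        aucs.append(float(_skm.roc_auc_score(labels == c, scores[:, j])))
    return float(np.mean(aucs))


def confusion_matrix(
    preds: Sequence,
    labels: Sequence,
    class_order: Optional[Sequence[str]] = None,
    normalize_rows: bool = False,
    round_digits: Optional[int] = None,
) -> np.ndarray:
    """Confusion counts (rows: true class), optionally row-normalized/rounded.

    A class with zero true members yields an all-zero row (with a warning)
    rather than NaNs.
    """
    preds, labels = np.asarray(preds), np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length")
    if class_order is None:
        class_order = sorted(np.unique(np.concatenate([labels, preds])))
    cm = _skm.confusion_matrix(labels, preds, labels=list(class_order)).astype(float)
    if normalize_rows:
        sums = cm.sum(axis=1, keepdims=True)
        empty = np.flatnonzero(sums[:, 0] == 0)
        for i in empty:
            logger.warning("confusion matrix: class %s has no true samples",
                           list(class_order)[i])
        sums[sums == 0] = 1.0
        cm = cm / sums
    if round_digits is not None:
        cm = np.round(cm, round_digits)
    return cm


def per_class_counts(preds: Sequence, labels: Sequence,
                     class_order: Sequence[str]) -> Dict[str, Dict[str, int]]:
    """One-vs-rest TP / FP / FN per class."""
    preds, labels = np.asarray(preds), np.asarray(labels)
    out = {}
    for c in class_order:
        tp = int(np.sum((preds == c) & (labels == c)))
        fp = int(np.sum((preds == c) & (labels != c)))
        fn = int(np.sum((preds != c) & (labels == c)))
        out[str(c)] = {"TP": tp, "FP": fp, "FN": fn}
    return out


@dataclass
class EvaluationReport:
    """All scores for one (algorithm, paradigm, representation) cell."""

    algorithm: Algorithm
    paradigm: Paradigm
    representation: Representation
    accuracy: float
    f1_macro: float
    roc_auc: float
    confusion: np.ndarray  # counts, class_order rows/cols
    class_order: Tuple[str, ...]
    per_class: Dict[str, Dict[str, int]]
    tuned_params: Optional[Dict[str, object]] = None
    dimension: Optional[int] = None
    roc_auc_convention: str = "macro one-vs-rest"

    def confusion_normalized(self, round_digits: int = 2) -> np.ndarray:
        sums = self.confusion.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return np.round(self.confusion / sums, round_digits)


@dataclass
class ExtremityReport:
    """2x2 upper/lower-limb aggregation of a four-muscle confusion matrix."""

    confusion: np.ndarray  # rows/cols (UPPER, LOWER), counts
    accuracy: float
    class_order: Tuple[str, str] = (Extremity.UPPER.value, Extremity.LOWER.value)


def evaluate_cell(
    preds: Predictions,
    y_test: np.ndarray,
    algorithm: Algorithm,
    paradigm: Paradigm,
    representation: Representation,
    tuned_params: Optional[Dict[str, object]] = None,
    dimension: Optional[int] = None,
) -> EvaluationReport:
    order = list(preds.classes)
    cm = confusion_matrix(preds.y_pred, y_test, class_order=order)
    return EvaluationReport(
        algorithm=algorithm,
        paradigm=paradigm,
        representation=representation,
        accuracy=accuracy(preds.y_pred, y_test),
        f1_macro=f1_macro(preds.y_pred, y_test),
        roc_auc=roc_auc(preds.scores, y_test, preds.classes),
        confusion=cm,
        class_order=tuple(order),
        per_class=per_class_counts(preds.y_pred, y_test, order),
        tuned_params=tuned_params,
        dimension=dimension,
    )


def extremity_report(report: EvaluationReport) -> ExtremityReport:
    """Sum a muscle-level confusion matrix across limbs (counts conserved)."""
    limb_of = {m.value: m.extremity.value for m in MuscleClass}
    limbs = (Extremity.UPPER.value, Extremity.LOWER.value)
    agg = np.zeros((2, 2))
    for i, ci in enumerate(report.class_order):
        for j, cj in enumerate(report.class_order):
            agg[limbs.index(limb_of[ci]), limbs.index(limb_of[cj])] += \
                report.confusion[i, j]
    total = agg.sum()
    acc = float(np.trace(agg) / total) if total else 0.0
    return ExtremityReport(confusion=agg, accuracy=acc)


def summary_table(reports: Mapping[Tuple[str, str, str], EvaluationReport]) -> pd.DataFrame:
    """Accuracy / F1 / ROC AUC per cell, laid out paradigm x algorithm rows
    and representation-metric columns."""
    rows = []
    for (algo, paradigm, rep), r in reports.items():
        rows.append({
            "paradigm": paradigm, "algorithm": algo, "representation": rep,
            "accuracy": round(r.accuracy, 4), "f1_macro": round(r.f1_macro, 4),
            "roc_auc": round(r.roc_auc, 4), "dimension": r.dimension,
        })
    df = pd.DataFrame(rows)
    return df.pivot_table(
        index=["paradigm", "algorithm"], columns="representation",
        values=["accuracy", "f1_macro", "roc_auc"], sort=False,
    ).swaplevel(axis=1).sort_index(axis=1, level=0)
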