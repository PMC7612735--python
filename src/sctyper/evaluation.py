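"""Classification metrics: per-class precision/recall/F1, median F1 summary,
epoch-wise learning curves and fine/coarse label-consistency checks.

The summary statistic reported throughout is the median of per-class F1 over
classes with nonzero support; the macro (mean) F1 is carried alongside for
transparency. Cells predicted "Unassigned" count as false negatives for their
true class and enter no class's precision denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classifier import (
    UNASSIGNED,
    CellTypeClassifier,
    TrainingConfig,
    _softmax,
)
from .data_model import LabelHierarchy, ValidationError
from .preprocessing import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "precision_recall_f1",
    "evaluate_labels",
    "f1_learning_curve",
    "hierarchy_consistency",
]


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # index: class; columns: precision, recall, f1, support
    median_f1: float
    macro_f1: float

    def to_tsv(self, path: str) -> None:
        self.per_class.rename_axis("class").reset_index().to_csv(path, sep="\t", index=False)


def confusion_counts(true_labels, predicted_labels) -> pd.DataFrame:
    """Count table with one row per true class and one column per predicted
    label ("Unassigned" allowed only as a column)."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("true and predicted label lists differ in length")
    if UNASSIGNED in true_labels:
        raise ValidationError(f"{UNASSIGNED!r} cannot appear as a true label")
    rows = sorted(set(true_labels))
    cols = sorted(set(predicted_labels) | set(rows))
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        table.loc[t, p] += 1
    return table


def precision_recall_f1(confusion: pd.DataFrame) -> MetricsReport:
    """Per-class precision, recall and F1 from a confusion table, with zero
    conventions P=0 (resp. R=0, F1=0) when the denominator vanishes; summary
    median taken over classes with support > 0."""
    if int(confusion.to_numpy().sum()) == 0:
        raise ValidationError("empty confusion table")
    classes = [c for c in confusion.columns if c != UNASSIGNED]
    classes = sorted(set(classes) | set(confusion.index))
    rows = []
    for c in classes:
        tp = int(confusion.loc[c, c]) if (c in confusion.index and c in confusion.columns) else 0
        pred_total = int(confusion[c].sum()) if c in confusion.columns else 0
        true_total = int(confusion.loc[c].sum()) if c in confusion.index else 0
        p = tp / pred_total if pred_total else 0.0
        r = tp / true_total if true_total else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        rows.append({"class": c, "precision": p, "recall": r, "f1": f1, "support": true_total})
    per_class = pd.DataFrame(rows).set_index("class")
    supported = per_class[per_class["support"] > 0]["f1"]
    median = float(np.median(supported)) if len(supported) else 0.0
    macro = float(supported.mean()) if len(supported) else 0.0
    return MetricsReport(per_class=per_class, median_f1=median, macro_f1=macro)


def evaluate_labels(true_labels, predicted_labels) -> MetricsReport:
    """Convenience: confusion table then metrics in one call."""
    return precision_recall_f1(confusion_counts(true_labels, predicted_labels))


def f1_learning_curve(
    X: NormalizedMatrix,
    labels,
    config: TrainingConfig,
) -> list[dict]:
    """Median validation F1 at every epoch boundary of a two-round fit.

    Cells are split once into train/validation (stratified by class, seeded by
    ``config.seed``, fraction ``config.validation_fraction``); the curve has one
    point per epoch per round. Classes absent from the validation split are
    excluded from the median with a warning.
    """
    labels = np.asarray(list(labels), dtype=object)
    idx_train, idx_val = train_test_split(
        np.arange(X.n_cells),
        test_size=config.validation_fraction,
        stratify=labels,
        random_state=config.seed % (2**32),
    )
    Xtr, ytr = X.values[idx_train], labels[idx_train]
    Xval, yval = X.values[idx_val], labels[idx_val]
    missing = set(labels) - set(yval)
    if missing:
        logger.warning("classes absent from validation split: %s", sorted(missing))

    est = CellTypeClassifier(
        batch_size=config.batch_size, epochs=config.epochs,
        l2_strength=config.l2_strength, learning_rate0=config.learning_rate0,
        lr_schedule=config.lr_schedule, n_top_genes=config.n_top_genes,
        two_round=True, random_state=config.seed,
    )
    curve: list[dict] = []

    def callback(epoch, W, b, sel=None):
        Xv = Xval if sel is None else Xval[:, sel]
        proba = _softmax(Xv @ W.T + b)
        pred = est.classes_[proba.argmax(axis=1)]
        report = evaluate_labels(yval, pred)
        curve.append({
            "round": 1 if sel is None else 2,
            "epoch": epoch,
            "median_f1": report.median_f1,
        })
        return report.median_f1

    est.fit(Xtr, ytr, epoch_callback=callback)
    return curve


def hierarchy_consistency(pred_low, pred_high, hierarchy: LabelHierarchy) -> float:
    """Fraction of cells whose fine-level prediction maps to their coarse-level
    prediction under the hierarchy; 1.0 (vacuous) on empty input."""
    pred_low = list(pred_low)
    pred_high = list(pred_high)
    if len(pred_low) != len(pred_high):
        raise ValidationError("prediction lists differ in length")
    if not pred_low:
        logger.warning("hierarchy_consistency on empty input; returning 1.0 vacuously")
        return 1.0
    mapped = hierarchy.to_high(pred_low)
    agree = sum(m == h for m, h in zip(mapped, pred_high))
    return agree / len(pred_low)
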