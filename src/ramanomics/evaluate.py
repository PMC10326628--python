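"""Classifier performance evaluation.

Two-class confusion matrix, per-class precision / recall / F1, per-class
accuracy (the class recall expressed as a percentage, as tabulated in
clinical-chemometrics reports), overall accuracy, and the ROC curve with
trapezoid AUC.  The ROC positive class defaults to ``pregnancy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from ramanomics.classify import CLASS_ORDER


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i][j] = number of spectra with true class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    per_class_accuracy_pct: dict[str, float]   # class recall as a percent
    overall_accuracy: float
    correct: int
    total: int
    roc: tuple[np.ndarray, np.ndarray] | None = None   # (fpr, tpr)
    auc: float | None = None

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation form: metrics to two decimals, accuracies in percent."""
        rnd = lambda d: {k: (round(v, ndigits) if np.isfinite(v) else None)
                         for k, v in d.items()}
        out = {
            "confusion": self.confusion.counts.astype(int).tolist(),
            "precision": rnd(self.precision),
            "recall": rnd(self.recall),
            "f1": rnd(self.f1),
            "per_class_accuracy_pct": rnd(self.per_class_accuracy_pct),
            "overall_accuracy_pct": round(100.0 * self.overall_accuracy, ndigits),
            "correct": self.correct,
            "total": self.total,
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, 3)
        return out


def confusion(preds, truths, classes: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    """Exact 2x2 confusion counts (rows true, columns predicted)."""
    preds = np.asarray(preds, dtype=object)
    truths = np.asarray(truths, dtype=object)
    if preds.size != truths.size or preds.size == 0:
        raise EvaluationError("predictions and truths must have equal, nonzero length")
    index = {c: i for i, c in enumerate(classes)}
    for arr, name in ((preds, "prediction"), (truths, "truth")):
        bad = set(arr) - set(classes)
        if bad:
            raise EvaluationError(f"{name} labels outside class set: {sorted(bad)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truths, preds):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """Precision / recall / F1 per class and overall accuracy from counts.

    A precision (no predictions of the class) or recall (no true
    instances) that is undefined is reported as NaN.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise EvaluationError("empty confusion matrix")
    precision, recall, f1, class_acc = {}, {}, {}, {}
    for i, cls in enumerate(cm.classes):
        pred_total = counts[:, i].sum()
        true_total = counts[i, :].sum()
        p = counts[i, i] / pred_total if pred_total else np.nan
        r = counts[i, i] / true_total if true_total else np.nan
        precision[cls] = float(p)
        recall[cls] = float(r)
        f1[cls] = float(2 * p * r / (p + r)) if (p + r) > 0 else (np.nan if np.isnan(p) or np.isnan(r) else 0.0)
        class_acc[cls] = float(100.0 * r)
    correct = int(np.trace(counts))
    total = cm.total
    return EvalReport(confusion=cm, precision=precision, recall=recall, f1=f1,
                      per_class_accuracy_pct=class_acc,
                      overall_accuracy=correct / total, correct=correct, total=total)


def roc_auc(scores, truths, positive: str = "pregnancy") -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoid AUC.

    ``scores`` are the predicted probabilities (or any monotone score)
    of the positive class.  Tied scores collapse onto one ROC vertex,
    which makes the trapezoid area equal the half-credit Mann-Whitney
    pair-count statistic.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=object)
    if not np.isfinite(scores).all():
        raise EvaluationError("non-finite scores")
    y = (truths == positive).astype(int)
    if y.min() == y.max():
        raise EvaluationError("both classes must be present for ROC/AUC")
    fpr, tpr, _ = roc_curve(y, scores)
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area


def evaluate_predictions(preds, truths, scores=None, positive: str = "pregnancy") -> EvalReport:
    """Full report: confusion-derived metrics plus ROC/AUC when scores given."""
    report = metrics(confusion(preds, truths))
    if scores is not None:
        fpr, tpr, area = roc_auc(scores, truths, positive=positive)
        report.roc = (fpr, tpr)
        report.auc = area
    return report
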