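"""Classification metrics: confusion matrix, one-vs-rest sensitivity and
specificity, accuracy, ROC/AUC, error histogram, and a paired-model
McNemar comparison.

Multi-class sensitivity/specificity are computed one-vs-rest per class and
macro-averaged (unweighted class mean); per-class values are always reported
alongside the macros, since a single headline number hides the averaging
scheme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "EvaluationReport",
    "McNemarResult",
    "confusion",
    "metrics_from_confusion",
    "roc_ovr",
    "error_histogram",
    "compare_models",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # (C, C): rows = true class, cols = predicted
    class_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.class_labels)
        if self.counts.shape != (C, C):
            raise ValueError("confusion counts must be C x C")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class EvaluationReport:
    confusion: ConfusionMatrix
    accuracy: float
    per_class_sensitivity: dict
    per_class_specificity: dict
    macro_sensitivity: float
    macro_specificity: float
    roc: list[ROCCurve] = field(default_factory=list)
    error_histogram: dict | None = None

    def to_dict(self) -> dict:
        return {
            "class_labels": [int(c) for c in self.confusion.class_labels],
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "per_class_sensitivity": {str(k): v for k, v in
                                      self.per_class_sensitivity.items()},
            "per_class_specificity": {str(k): v for k, v in
                                      self.per_class_specificity.items()},
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "auc": [r.auc for r in self.roc],
            "error_histogram": self.error_histogram,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion(true_labels, predicted_labels, class_labels) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted as j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    index = {c: k for k, c in enumerate(class_labels)}
    C = len(class_labels)
    counts = np.zeros((C, C), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: true={t!r}, pred={p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_labels=list(class_labels))


def metrics_from_confusion(cm: ConfusionMatrix) -> EvaluationReport:
    """One-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP) per
    class, overall accuracy trace/total, and unweighted macro means.

    A class with zero true members has undefined sensitivity; it is excluded
    from the macro mean with a logged warning.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    sens, spec = {}, {}
    sens_vals, spec_vals = [], []
    for k, label in enumerate(cm.class_labels):
        TP = cm.counts[k, k]
        FN = cm.counts[k, :].sum() - TP
        FP = cm.counts[:, k].sum() - TP
        TN = total - TP - FN - FP
        if TP + FN > 0:
            s = TP / (TP + FN)
            sens[label] = float(s)
            sens_vals.append(s)
        else:
            logger.warning("class %r has no true members; sensitivity "
                           "undefined, excluded from macro mean", label)
            sens[label] = float("nan")
        if TN + FP > 0:
            sp = TN / (TN + FP)
            spec[label] = float(sp)
            spec_vals.append(sp)
        else:
            spec[label] = float("nan")
    return EvaluationReport(
        confusion=cm,
        accuracy=float(np.trace(cm.counts) / total),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        macro_sensitivity=float(np.mean(sens_vals)),
        macro_specificity=float(np.mean(spec_vals)),
    )


def roc_ovr(true_labels, prob_matrix, class_index: int,
            class_labels) -> ROCCurve:
    """One-vs-rest ROC for ``class_labels[class_index]``: threshold sweep
    over the unique scores, trapezoidal AUC, endpoints (0,0) and (1,1)."""
    true_labels = np.asarray(true_labels)
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    pos = (true_labels == class_labels[class_index]).astype(int)
    if pos.sum() == 0 or pos.sum() == pos.size:
        raise ValueError(
            "ROC undefined: need both positive and negative examples"
        )
    scores = prob_matrix[:, class_index]
    fpr, tpr, thr = _sk_roc_curve(pos, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def error_histogram(true_labels, prob_matrix, bins: int = 20,
                    class_labels=None) -> dict:
    """Histogram of per-sample error ``e = P(true class) - 1`` over
    ``bins`` equal-width bins spanning the observed range.

    Returns bin edges, counts, and the index of the bin containing zero
    error.  A degenerate range (all errors equal) is widened by ±0.5.
    """
    true_labels = np.asarray(true_labels)
    prob_matrix = np.asarray(prob_matrix, dtype=float)
    if class_labels is None:
        class_labels = sorted(np.unique(true_labels))
    index = {c: k for k, c in enumerate(class_labels)}
    e = np.array([prob_matrix[n, index[t]] - 1.0
                  for n, t in enumerate(true_labels)])
    lo, hi = float(e.min()), float(e.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(e, bins=bins, range=(lo, hi))
    zero_bin = int(np.clip(np.searchsorted(edges, 0.0, side="right") - 1,
                           0, bins - 1))
    return {"edges": edges, "counts": counts, "zero_bin": zero_bin}


@dataclass
class McNemarResult:
    b: int            # model A correct, model B wrong
    c: int            # model A wrong, model B correct
    statistic: int    # b - c
    p_value: float


def compare_models(preds_a, preds_b, true_labels) -> McNemarResult:
    """Exact McNemar test on the discordant pairs of correct/incorrect
    predictions of two classifiers on the same samples.

    With no discordant pairs there is no evidence of a difference and
    p = 1 by convention.
    """
    preds_a = np.asarray(preds_a)
    preds_b = np.asarray(preds_b)
    true_labels = np.asarray(true_labels)
    if not (preds_a.shape == preds_b.shape == true_labels.shape):
        raise ValueError("prediction and truth vectors must have equal length")
    ok_a = preds_a == true_labels
    ok_b = preds_b == true_labels
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        p = 1.0
    else:
        p = float(binomtest(b, b + c, 0.5).pvalue)
    return McNemarResult(b=b, c=c, statistic=b - c, p_value=p)


def evaluate(true_labels, predicted_labels, prob_matrix,
             class_labels) -> EvaluationReport:
    """Full report: confusion, rates, per-class one-vs-rest ROC curves and a
    20-bin error histogram."""
    cm = confusion(true_labels, predicted_labels, class_labels)
    report = metrics_from_confusion(cm)
    for k in range(len(class_labels)):
        try:
            report.roc.append(roc_ovr(true_labels, prob_matrix, k,
                                      class_labels))
        except ValueError:
            logger.warning("ROC undefined for class %r; skipped",
                           class_labels[k])
    hist = error_histogram(true_labels, prob_matrix, bins=20,
                           class_labels=class_labels)
    report.error_histogram = {
        "edges": hist["edges"].tolist(),
        "counts": hist["counts"].tolist(),
        "zero_bin": hist["zero_bin"],
    }
    return report
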