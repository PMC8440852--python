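"""Leave-one-subject-out evaluation harness, metrics and paired testing.

Classification metrics follow the confusion-matrix definitions used in the
pain-assessment literature: for multi-class problems, accuracy, precision
and recall are one-vs-rest per-class values averaged over the c classes
(note this "accuracy" is an averaged per-class binary accuracy, not plain
top-1 accuracy, which is reported alongside as `top1`), and the F1-score
is the harmonic mean of the averaged precision and recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

log = logging.getLogger(__name__)

__all__ = [
    "FoldResult", "loso_folds", "classification_metrics",
    "regression_metrics", "compare_models", "aggregate_report",
]


def loso_folds(subjects) -> list:
    """One (train_subjects, test_subject) pair per subject.

    `subjects` may be an iterable of subject ids (duplicates allowed) or any
    object with a ``subjects()`` method.
    """
    if hasattr(subjects, "subjects"):
        uniq = list(subjects.subjects())
    else:
        uniq = sorted(set(subjects))
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    return [
        (tuple(s for s in uniq if s != test), test)
        for test in uniq
    ]


def _binary_counts(y_true, y_pred, positive):
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    return tp, tn, fp, fn


def _safe_div(num, den, name):
    if den == 0:
        log.warning("zero denominator in %s; defining the metric as 0", name)
        return 0.0
    return num / den


def classification_metrics(y_true, y_pred, classes=None) -> dict:
    """Accuracy/precision/recall/F1 from confusion counts.

    Binary: the positive class is the higher label (the stronger
    elicitation). Multi-class: one-vs-rest values averaged over classes;
    F1 is computed from the averaged precision and recall.
    """
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.sort(np.asarray(classes))
    c = len(classes)
    if c == 2:
        tp, tn, fp, fn = _binary_counts(y_true, y_pred, positive=classes[-1])
        acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
        prec = _safe_div(tp, tp + fp, "precision")
        rec = _safe_div(tp, tp + fn, "recall")
    else:
        accs, precs, recs = [], [], []
        for cls in classes:
            tp, tn, fp, fn = _binary_counts(y_true, y_pred, positive=cls)
            accs.append(_safe_div(tp + tn, tp + tn + fp + fn, "accuracy"))
            precs.append(_safe_div(tp, tp + fp, f"precision[{cls}]"))
            recs.append(_safe_div(tp, tp + fn, f"recall[{cls}]"))
        acc, prec, rec = np.mean(accs), np.mean(precs), np.mean(recs)
    f1 = _safe_div(2 * prec * rec, prec + rec, "F1")
    return {
        "accuracy": float(acc), "precision": float(prec),
        "recall": float(rec), "f1": float(f1),
        "top1": float(np.mean(y_true == y_pred)),
    }


def regression_metrics(predictions, targets) -> dict:
    """Mean absolute error and root-mean-square error."""
    predictions, targets = np.asarray(predictions, float), np.asarray(targets, float)
    if len(predictions) == 0 or len(predictions) != len(targets):
        raise ValueError("need equal-length, non-empty prediction/target arrays")
    err = targets - predictions
    return {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err**2))),
    }


@dataclass
class FoldResult:
    """Predictions and metrics for one held-out subject."""

    test_subject: str
    y_true: np.ndarray
    y_pred: np.ndarray
    task: str = "classification"
    classes: np.ndarray = None
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true)
        self.y_pred = np.asarray(self.y_pred)
        if not self.metrics:
            if self.task == "classification":
                self.metrics = classification_metrics(
                    self.y_true, self.y_pred, self.classes
                )
            else:
                self.metrics = regression_metrics(self.y_pred, self.y_true)

    def counts(self) -> dict:
        """Binary confusion counts (positive = highest class label)."""
        classes = (np.sort(self.classes) if self.classes is not None
                   else np.unique(np.concatenate([self.y_true, self.y_pred])))
        tp, tn, fp, fn = _binary_counts(self.y_true, self.y_pred, classes[-1])
        return {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def compare_models(metric_a, metric_b, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test on paired per-fold metrics.

    Uses the exact null distribution for n <= 25 (when free of zeros/ties)
    and the normal approximation with continuity correction otherwise.
    All-zero differences are degenerate and reported as p = 1.
    """
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need paired metric vectors of equal length >= 5")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = scipy.stats.wilcoxon(a, b, alternative=alternative, method=method)
    except ValueError:
        res = scipy.stats.wilcoxon(a, b, alternative=alternative,
                                   method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def aggregate_report(fold_results) -> dict:
    """Per-metric mean and standard deviation across folds."""
    folds = list(fold_results)
    if not folds:
        raise ValueError("need at least one fold")
    names = folds[0].metrics.keys()
    return {
        name: {
            "mean": float(np.mean([f.metrics[name] for f in folds])),
            "sd": float(np.std([f.metrics[name] for f in folds])),
        }
        for name in names
    }
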