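"""Imbalanced-multiclass evaluation metrics.

All scalar metrics are computed from a C×C confusion matrix (rows =
true class, columns = predicted class), which may hold real values so
that averaged row-percent matrices can be evaluated directly.  Per
class c, with TP/FP/FN/TN taken one-vs-rest:

    precision = TP/(TP+FP)            recall (TPR) = TP/(TP+FN)
    specificity (TNR) = TN/(TN+FP)    F1 = 2PR/(P+R)
    Jaccard = TP/(TP+FP+FN)           G-mean = sqrt(recall * specificity)

Averaging is macro (unweighted class mean) or weighted (by true-class
proportions); overall accuracy is the class-size-weighted average TPR,
identically trace/total.  Agreement statistics are Cohen's kappa and
the Gorodkin multiclass generalization of the Matthews correlation
coefficient.  ROC/PR curves and AUCs are one-vs-rest with micro
(pooled) and macro (common-grid average) variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .partitioning import round_half_away

__all__ = [
    "ConfusionMatrix", "confusion_from_predictions", "percent_views",
    "percent_to_counts", "per_class_metrics", "average_metrics",
    "accuracy_weighted_tpr", "kappa_and_mcc", "curve_aucs", "metric_report",
]

PER_CLASS_METRICS = ("precision", "recall", "specificity", "f1", "jaccard", "g_mean")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # C×C, rows = true class; may be real-valued
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C×C matching class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


def confusion_from_predictions(true_labels, predicted_labels,
                               class_names: list[str]) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true class i predicted as class j}."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label arrays must have equal length")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)))
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class list: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, list(class_names))


def percent_views(cm: ConfusionMatrix) -> np.ndarray:
    """Row-percent matrix: 100 * counts / row sum."""
    rows = cm.row_sums()
    if (rows == 0).any():
        raise ValueError("percent view undefined for an empty true class")
    return 100.0 * cm.counts / rows[:, None]


def percent_to_counts(percent: np.ndarray, class_sizes,
                      class_names: list[str] | None = None) -> ConfusionMatrix:
    """Rescale a row-percent matrix back to (real-valued) counts."""
    percent = np.asarray(percent, dtype=np.float64)
    class_sizes = np.asarray(class_sizes, dtype=np.float64)
    sums = percent.sum(axis=1)
    if np.any(np.abs(sums - 100.0) > 2.0):
        raise ValueError("percent rows must sum to ~100 (±2 for rounded inputs)")
    counts = percent * class_sizes[:, None] / 100.0
    names = class_names or [f"class_{i}" for i in range(len(class_sizes))]
    return ConfusionMatrix(counts, list(names))


def _one_vs_rest(cm: ConfusionMatrix) -> tuple[np.ndarray, ...]:
    m = cm.counts
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num: np.ndarray, den: np.ndarray, flags: list[str], name: str,
              class_names: list[str]) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    bad = den == 0
    np.divide(num, den, out=out, where=~bad)
    for i in np.nonzero(bad)[0]:
        flags.append(f"{name}[{class_names[i]}]")
    return out


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """The six per-class metrics; 0/0 cells report 0 and raise a warning."""
    tp, fp, fn, tn = _one_vs_rest(cm)
    flags: list[str] = []
    names = cm.class_names
    precision = _safe_div(tp, tp + fp, flags, "precision", names)
    recall = _safe_div(tp, tp + fn, flags, "recall", names)
    specificity = _safe_div(tn, tn + fp, flags, "specificity", names)
    f1 = _safe_div(2 * precision * recall, precision + recall, flags, "f1", names)
    jaccard = _safe_div(tp, tp + fp + fn, flags, "jaccard", names)
    g_mean = np.sqrt(recall * specificity)
    if flags:
        warnings.warn(f"degenerate 0/0 metric cells reported as 0: {flags}",
                      RuntimeWarning, stacklevel=2)
    return {"precision": precision, "recall": recall, "specificity": specificity,
            "f1": f1, "jaccard": jaccard, "g_mean": g_mean,
            "_degenerate": np.array(flags, dtype=object)}


def accuracy_weighted_tpr(cm: ConfusionMatrix) -> float:
    """Overall accuracy = class-size-weighted average TPR = trace/total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def average_metrics(cm: ConfusionMatrix, scheme: str = "macro") -> dict[str, float]:
    """Macro or weighted averages of the per-class metrics, plus accuracy.

    Classes absent from the truth are excluded from macro averaging.
    """
    if scheme not in ("macro", "weighted", "micro"):
        raise ValueError("scheme must be macro, weighted or micro")
    per = per_class_metrics(cm)
    rows = cm.row_sums()
    present = rows > 0
    out: dict[str, float] = {}
    if scheme == "micro":
        out["accuracy"] = accuracy_weighted_tpr(cm)
        return out
    if scheme == "macro":
        weights = present / present.sum()
    else:
        weights = rows / rows.sum()
    for name in PER_CLASS_METRICS:
        out[name] = float((per[name] * weights).sum())
    out["accuracy"] = accuracy_weighted_tpr(cm)
    return out


def kappa_and_mcc(cm: ConfusionMatrix) -> tuple[float, float]:
    """(Cohen's kappa, Gorodkin multiclass Matthews coefficient)."""
    n = cm.total
    if n <= 0:
        raise ValueError("confusion matrix total must be > 0")
    rows = cm.row_sums()
    cols = cm.counts.sum(axis=0)
    trace = np.trace(cm.counts)
    p_o = trace / n
    p_e = float((rows * cols).sum()) / n ** 2
    if p_e >= 1.0:
        warnings.warn("chance agreement p_e = 1; kappa undefined, reporting 0",
                      RuntimeWarning, stacklevel=2)
        cks = 0.0
    else:
        cks = float((p_o - p_e) / (1.0 - p_e))
    denom = np.sqrt(float(n ** 2 - (rows ** 2).sum()) * float(n ** 2 - (cols ** 2).sum()))
    if denom == 0:
        warnings.warn("degenerate marginals; MCC undefined, reporting 0",
                      RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = float((n * trace - (rows * cols).sum()) / denom)
    return cks, mcc


def curve_aucs(scores: np.ndarray, true_labels, class_names: list[str],
               kind: str = "ROC") -> dict:
    """One-vs-rest ROC or PR curves and AUCs with micro/macro averaging.

    ``scores`` is n×C with rows ~summing to 1; returns per-class AUCs
    (NaN-flagged for classes absent from the truth), micro AUC from the
    pooled (score, indicator) pairs, macro AUC, and the curve points.
    ROC AUC is trapezoidal, PR AUC uses step interpolation.
    """
    scores = np.asarray(scores, dtype=np.float64)
    true_labels = np.asarray(true_labels)
    if scores.ndim != 2 or scores.shape[1] != len(class_names):
        raise ValueError("scores must be n×C")
    if np.any(np.abs(scores.sum(axis=1) - 1.0) > 1e-3):
        raise ValueError("score rows must sum to ~1")
    onehot = np.stack([(true_labels == c).astype(float) for c in class_names], axis=1)
    out: dict = {"per_class": {}, "curves": {}}
    per_auc = []
    for j, c in enumerate(class_names):
        if onehot[:, j].sum() == 0 or onehot[:, j].sum() == len(true_labels):
            out["per_class"][c] = float("nan")
            continue
        if kind.upper() == "ROC":
            fpr, tpr, _ = roc_curve(onehot[:, j], scores[:, j])
            out["curves"][c] = (fpr, tpr)
            val = float(_sk_auc(fpr, tpr))
        elif kind.upper() == "PR":
            prec, rec, _ = precision_recall_curve(onehot[:, j], scores[:, j])
            out["curves"][c] = (rec, prec)
            # step interpolation: sum of P_i * (R_i - R_{i-1})
            val = float(-np.sum(np.diff(rec) * prec[:-1]))
        else:
            raise ValueError("kind must be 'ROC' or 'PR'")
        out["per_class"][c] = val
        per_auc.append(val)
    # micro: pool all one-vs-rest (score, indicator) pairs
    flat_y, flat_s = onehot.ravel(), scores.ravel()
    if kind.upper() == "ROC":
        fpr, tpr, _ = roc_curve(flat_y, flat_s)
        out["curves"]["micro"] = (fpr, tpr)
        out["micro"] = float(_sk_auc(fpr, tpr))
        grid = np.linspace(0.0, 1.0, 201)
        interp = [np.interp(grid, *out["curves"][c]) for c in class_names
                  if c in out["curves"]]
        if interp:
            mean_tpr = np.mean(interp, axis=0)
            out["curves"]["macro"] = (grid, mean_tpr)
            out["macro"] = float(_sk_auc(grid, mean_tpr))
        else:
            out["macro"] = float("nan")
    else:
        prec, rec, _ = precision_recall_curve(flat_y, flat_s)
        out["curves"]["micro"] = (rec, prec)
        out["micro"] = float(-np.sum(np.diff(rec) * prec[:-1]))
        out["macro"] = float(np.mean(per_auc)) if per_auc else float("nan")
    return out


def metric_report(cm: ConfusionMatrix, scores: np.ndarray | None = None,
                  true_labels=None) -> dict[str, float]:
    """One flat row of every reported metric (percent-scale rates).

    Mirrors the per-fold report layout: macro and weighted variants of
    the six per-class metrics, micro accuracy, MCC and kappa, plus ROC
    and PR AUCs when probability scores are supplied.
    """
    macro = average_metrics(cm, "macro")
    weighted = average_metrics(cm, "weighted")
    cks, mcc = kappa_and_mcc(cm)
    row: dict[str, float] = {}
    for name in PER_CLASS_METRICS:
        row[f"{name}_macro"] = 100.0 * macro[name]
        row[f"{name}_weighted"] = 100.0 * weighted[name]
    row["accuracy"] = 100.0 * macro["accuracy"]
    row["mcc"] = mcc
    row["cks"] = cks
    if scores is not None and true_labels is not None:
        roc = curve_aucs(scores, true_labels, cm.class_names, kind="ROC")
        pr = curve_aucs(scores, true_labels, cm.class_names, kind="PR")
        row["roc_auc_macro"] = 100.0 * roc["macro"]
        row["roc_auc_micro"] = 100.0 * roc["micro"]
        row["pr_auc_micro"] = 100.0 * pr["micro"]
    return row


def round_percent(x: float) -> int:
    """Half-away-from-zero rounding to integer percent for report tables."""
    return round_half_away(x)
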