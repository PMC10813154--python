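"""Confusion-count metrics for binary and multi-class evaluation.

Nine metrics: Accuracy, Precision, Recall, F1 (all in %), plus Kappa,
MCC, CSI and Gmean, and a rank-based AUC.  The binary forms are
computed directly from TP/TN/FP/FN:

    Accuracy = (TP+TN)/(TP+TN+FP+FN)
    Precision = TP/(TP+FP),  Recall = TP/(TP+FN)
    F1 = 2 P R / (P + R)
    Kappa = 2 (TP*TN - FN*FP) / [(TP+FP)(FP+TN) + (TP+FN)(FN+TN)]
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    CSI = TP/(TP+FP+FN)
    Gmean = sqrt(Recall * Specificity)

MCC spans [-1, 1].  Specificity is TN/(TN+FP) by default; the variant
TN/(FN+TN) is selectable as ``specificity_mode="as_printed"`` for
comparison with sources that use that form.  Zero-denominator ratios
are reported as an explicit ``None`` sentinel, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion_from_predictions",
           "binary_metrics", "auc_score", "multiclass_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of one binary evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts must cover at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """The nine evaluation metrics of one experiment cell.

    Accuracy/Precision/Recall/F1 are percentages in [0, 100]; Kappa and
    MCC are in [-1, 1]; CSI, Gmean and AUC in [0, 1].  ``None`` marks a
    metric undefined by a zero denominator.
    """

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    kappa: float | None = None
    mcc: float | None = None
    csi: float | None = None
    gmean: float | None = None
    auc: float | None = None
    specificity_mode: str = "standard"
    auc_source: str = "scores"

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_from_predictions(y_true, y_pred, positive) -> ConfusionCounts:
    """Count TP/TN/FP/FN with respect to the declared positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 1:
        raise ValueError("empty label vectors")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den != 0 else None


def binary_metrics(c: ConfusionCounts, specificity_mode: str = "standard") -> MetricReport:
    """Evaluate the eight confusion-count metrics (AUC left unset)."""
    if specificity_mode not in ("standard", "as_printed"):
        raise ValueError(f"unknown specificity mode {specificity_mode!r}")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    accuracy = (tp + tn) / c.total * 100.0
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall) * 100.0
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    kappa = _ratio(2.0 * (tp * tn - fn * fp),
                   (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn))
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    csi = _ratio(tp, tp + fp + fn)
    if specificity_mode == "standard":
        spec = _ratio(tn, tn + fp)
    else:
        spec = _ratio(tn, fn + tn)
    gmean = np.sqrt(recall * spec) if recall is not None and spec is not None else None
    return MetricReport(
        accuracy=accuracy,
        precision=None if precision is None else precision * 100.0,
        recall=None if recall is None else recall * 100.0,
        f1=f1,
        kappa=kappa,
        mcc=mcc,
        csi=csi,
        gmean=gmean,
        specificity_mode=specificity_mode,
    )


def auc_score(y_true, scores) -> float:
    """Rank-based AUC: P(score of random positive > random negative).

    Ties count one half; equals trapezoidal integration of the ROC
    curve.  Requires both classes present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    classes = np.unique(y_true)
    if len(classes) != 2:
        raise ValueError("AUC needs exactly two classes present")
    pos = y_true == classes.max() if y_true.dtype.kind in "biu" else y_true == classes[-1]
    # interpret the lexically/numerically larger class label as positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_binary(y_true, scores, positive) -> float:
    """AUC with an explicitly declared positive class."""
    y_true = np.asarray(y_true)
    return auc_score((y_true == positive).astype(int), np.asarray(scores, float))


def multiclass_metrics(y_true, y_pred, scores=None, classes=None) -> MetricReport:
    """Multi-class generalisation of the nine-metric report.

    Accuracy is micro (pooled); Precision/Recall/F1 are weighted by
    class size; Kappa and MCC use their multi-class forms; AUC is
    one-vs-rest weighted when a score matrix is given; CSI and Gmean
    are macro averages of the per-class binary values.
    """
    from sklearn.metrics import (
        accuracy_score, cohen_kappa_score, f1_score, matthews_corrcoef,
        precision_score, recall_score, roc_auc_score,
    )

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    present = np.unique(y_true)
    if len(present) < 2:
        raise ValueError("multi-class metrics need >= 2 classes present")
    classes = list(classes) if classes is not None else list(present)
    accuracy = accuracy_score(y_true, y_pred) * 100.0
    precision = precision_score(y_true, y_pred, average="weighted",
                                zero_division=0) * 100.0
    recall = recall_score(y_true, y_pred, average="weighted",
                          zero_division=0) * 100.0
    f1 = f1_score(y_true, y_pred, average="weighted", zero_division=0) * 100.0
    kappa = cohen_kappa_score(y_true, y_pred)
    mcc = matthews_corrcoef(y_true, y_pred)
    csis, gmeans = [], []
    for cls in present:
        c = confusion_from_predictions(y_true, y_pred, cls)
        rep = binary_metrics(c)
        csis.append(0.0 if rep.csi is None else rep.csi)
        gmeans.append(0.0 if rep.gmean is None else rep.gmean)
    auc = None
    auc_source = "none"
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        try:
            if len(present) == 2 and scores.ndim == 2:
                scores = scores[:, list(classes).index(present[1])]
            auc = float(roc_auc_score(y_true, scores, multi_class="ovr",
                                      average="weighted", labels=classes))
            auc_source = "scores"
        except ValueError:
            auc = None
    return MetricReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        kappa=kappa, mcc=mcc, csi=float(np.mean(csis)),
        gmean=float(np.mean(gmeans)), auc=auc, auc_source=auc_source,
    )
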