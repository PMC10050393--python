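"""Ground-truth label logic and evaluation metrics for HER2 IHC scoring.

Clinical labelling: IHC scores 0 and 1 are HER2-negative, score 3 is
HER2-positive, and equivocal score-2 spots are resolved by in-situ
hybridisation (ISH) — positive when the HER2/CEN17 signal ratio is >= 2.0 or
the mean HER2 signal count is >= 6.0 (signals averaged over 20 tumour
cells), negative otherwise.

Metric conventions (chosen to reproduce the reference tabulations exactly):
confusion matrices are oriented *predicted x true*; "balanced accuracy" is
the unweighted macro-average of per-class recalls, while precision, recall
and F1 are averaged with support weights (true-class counts / n).  Note the
support-weighted recall is algebraically the plain overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCORES = (0, 1, 2, 3)

#: ISH positivity thresholds
ISH_RATIO_THRESHOLD = 2.0
ISH_SIGNAL_THRESHOLD = 6.0


class UnresolvedLabelError(ValueError):
    """A score-2 spot lacks both an explicit status and ISH counts."""


def ish_call(her2_signals: float, cen17_signals: float) -> int:
    """HER2 status from ISH signal counts: positive iff HER2/CEN17 >= 2.0
    or HER2 signals >= 6.0."""
    if cen17_signals <= 0:
        raise ValueError(f"cen17_signals must be positive, got {cen17_signals}")
    if her2_signals <= 0:
        raise ValueError(f"her2_signals must be positive, got {her2_signals}")
    ratio = her2_signals / cen17_signals
    return int(ratio >= ISH_RATIO_THRESHOLD or her2_signals >= ISH_SIGNAL_THRESHOLD)


def score_to_status(
    score: int,
    ish_status: int | None = None,
    her2_signals: float | None = None,
    cen17_signals: float | None = None,
) -> int:
    """Map an IHC score to binary HER2 status.

    Scores 0/1 -> negative, 3 -> positive.  Score 2 requires either an
    explicit ISH-derived status or HER2/CEN17 signal counts.
    """
    if score not in SCORES:
        raise ValueError(f"IHC score must be one of {SCORES}, got {score!r}")
    if score in (0, 1):
        return 0
    if score == 3:
        return 1
    if ish_status is not None:
        if ish_status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {ish_status!r}")
        return int(ish_status)
    if her2_signals is not None and cen17_signals is not None:
        return ish_call(her2_signals, cen17_signals)
    raise UnresolvedLabelError(
        "score-2 spot needs ISH information (status or signal counts)"
    )


@dataclass
class SpotLabel:
    """Ground truth for one spot; status derived from the score when absent."""

    spot_id: str
    ihc_score: int
    her2_status: int | None = None
    her2_signals: float | None = None
    cen17_signals: float | None = None

    def __post_init__(self) -> None:
        if self.ihc_score not in SCORES:
            raise ValueError(
                f"spot {self.spot_id!r}: invalid IHC score {self.ihc_score!r}"
            )
        derived = None
        if self.ihc_score != 2 or self.her2_status is None:
            derived = score_to_status(
                self.ihc_score,
                ish_status=self.her2_status if self.ihc_score == 2 else None,
                her2_signals=self.her2_signals,
                cen17_signals=self.cen17_signals,
            )
        if self.her2_status is None:
            self.her2_status = derived
        elif derived is not None and self.her2_status != derived:
            raise ValueError(
                f"spot {self.spot_id!r}: supplied status {self.her2_status} "
                f"contradicts score/ISH-derived status {derived}"
            )
        self.her2_status = int(self.her2_status)


# ---------------------------------------------------------------------------
# Metrics


def confusion(y_true, y_pred, classes) -> np.ndarray:
    """Confusion counts oriented predicted x true: entry (i, j) counts spots
    predicted ``classes[i]`` whose true label is ``classes[j]``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class list: true={t!r} pred={p!r}")
        mat[index[p], index[t]] += 1
    return mat


def balanced_accuracy(conf: np.ndarray) -> float:
    """Unweighted mean of per-class recalls (predicted x true orientation)."""
    conf = np.asarray(conf)
    true_counts = conf.sum(axis=0)
    if np.any(true_counts == 0):
        raise ValueError("every true class needs at least one sample")
    recalls = np.diag(conf) / true_counts
    return float(recalls.mean())


def weighted_metrics(conf: np.ndarray) -> tuple[float, float, float]:
    """Support-weighted (precision, recall, F1) from a predicted x true
    confusion matrix; weights are true-class counts / n.  Classes never
    predicted get precision 0."""
    conf = np.asarray(conf, dtype=float)
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    true_counts = conf.sum(axis=0)
    pred_counts = conf.sum(axis=1)
    diag = np.diag(conf)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_counts > 0, diag / np.maximum(pred_counts, 1e-300), 0.0)
        recall = np.where(true_counts > 0, diag / np.maximum(true_counts, 1e-300), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    weights = true_counts / n
    return (
        float(weights @ precision),
        float(weights @ recall),
        float(weights @ f1),
    )


def roc_one_vs_all(probabilities: np.ndarray, y_true, classes=None):
    """Per-class one-vs-all ROC curves and trapezoid AUCs.

    ``probabilities`` is n x C with rows summing to one; column order follows
    ``classes`` (default: sorted unique true labels padded to C columns is
    not attempted — pass ``classes`` explicitly when some class is absent).
    Returns ``{class: {"fpr": ..., "tpr": ..., "auc": float | None}}``; a
    class absent from ``y_true`` has undefined AUC, reported as ``None``.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y_true = np.asarray(y_true)
    if probabilities.ndim != 2 or probabilities.shape[0] != len(y_true):
        raise ValueError("probabilities must be n x C aligned with y_true")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if classes is None:
        classes = sorted(np.unique(y_true).tolist())
    if len(classes) != probabilities.shape[1]:
        raise ValueError("classes length must match probability columns")
    out = {}
    for j, c in enumerate(classes):
        pos = (y_true == c).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            out[c] = {"fpr": None, "tpr": None, "auc": None}
            continue
        fpr, tpr = _roc_curve(pos, probabilities[:, j])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(np.trapezoid(tpr, fpr))}
    return out


def _roc_curve(pos: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC by descending-threshold sweep; tied scores grouped into one step."""
    order = np.argsort(-score, kind="stable")
    score_s, pos_s = score[order], pos[order]
    distinct = np.where(np.diff(score_s))[0]
    idx = np.r_[distinct, len(score_s) - 1]
    tps = np.cumsum(pos_s)[idx]
    fps = np.cumsum(1 - pos_s)[idx]
    tpr = np.r_[0.0, tps / tps[-1]]
    fpr = np.r_[0.0, fps / fps[-1]]
    return fpr, tpr


@dataclass
class MetricsReport:
    """Confusion matrix (predicted x true) and the scalar summary metrics."""

    classes: list
    confusion: np.ndarray
    balanced_accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    per_class_auc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": [int(c) if isinstance(c, (int, np.integer)) else c
                        for c in self.classes],
            "confusion_predicted_x_true": self.confusion.tolist(),
            "balanced_accuracy": self.balanced_accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class_auc": {str(k): v["auc"] if isinstance(v, dict) else v
                              for k, v in self.per_class_auc.items()},
        }


def compute_report(y_true, y_pred, classes=None,
                   probabilities: np.ndarray | None = None) -> MetricsReport:
    """One-stop evaluation: confusion, balanced accuracy, support-weighted
    precision/recall/F1, and (when probabilities are given) per-class AUC."""
    if classes is None:
        classes = sorted(set(np.asarray(y_true).tolist())
                         | set(np.asarray(y_pred).tolist()))
    conf = confusion(y_true, y_pred, classes)
    prec, rec, f1 = weighted_metrics(conf)
    auc = {}
    if probabilities is not None:
        auc = roc_one_vs_all(probabilities, y_true, classes)
    return MetricsReport(
        classes=list(classes),
        confusion=conf,
        balanced_accuracy=balanced_accuracy(conf),
        weighted_precision=prec,
        weighted_recall=rec,
        weighted_f1=f1,
        per_class_auc=auc,
    )
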