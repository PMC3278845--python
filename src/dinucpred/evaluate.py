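"""ROC analysis, peak-F-score operating points, and precision calibration.

AUC is computed with the Mann-Whitney rank statistic (midranks for tied
scores), which equals the trapezoidal area under the ROC curve; both the
curve and the statistic are exposed.  Precision calibration maps a raw
prediction score, used as a cutoff, to the precision TP/(TP+FP) among
predictions at or above it — the empirical probability that a prediction
at that score is a true contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "PrecisionCalibration",
    "roc_auc",
    "peak_fscore",
    "calibrate_precision",
]


@dataclass
class ROCCurve:
    """ROC points (FPR, TPR) over all cutoffs and the area under them."""

    points: np.ndarray  # (k, 2) columns fpr, tpr; starts (0,0) ends (1,1)
    auc: float

    def trapezoid_area(self) -> float:
        fpr, tpr = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(tpr, fpr))


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    f1: float


@dataclass
class PrecisionCalibration:
    """Per-class step function score-cutoff -> precision.

    ``table[klass]`` is an array of (cutoff, precision, support) rows
    sorted by cutoff, or None when the class had no positives in the
    calibration data.
    """

    table: dict[str, np.ndarray | None]

    def precision_at(self, klass: str, score: float) -> float | None:
        tab = self.table.get(klass)
        if tab is None:
            return None
        idx = np.searchsorted(tab[:, 0], score, side="right") - 1
        if idx < 0:
            return float(tab[0, 1])
        return float(tab[idx, 1])


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    return scores, labels


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve over all distinct cutoffs, AUC by midrank statistic.

    A point is generated for each distinct score value (prediction
    positive when score >= cutoff), bracketed by (0,0) and (1,1).
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # midranks for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(1 - l_sorted)
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    points = np.vstack([[0.0, 0.0], np.column_stack([fpr, tpr])])
    return ROCCurve(points=points, auc=float(auc))


def peak_fscore(scores, labels) -> OperatingPoint:
    """Operating point maximising F1 over all cutoffs (ties -> higher cutoff).

    A prediction is positive when its score >= cutoff; cutoffs are the
    distinct observed scores.
    """
    scores, labels = _check_binary(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(1 - l_sorted)
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    best: OperatingPoint | None = None
    for k in distinct:
        tpk, fpk = int(tp[k]), int(fp[k])
        prec = tpk / (tpk + fpk)
        sens = tpk / n_pos
        f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
        spec = (n_neg - fpk) / n_neg
        # strictly-better wins; on ties the higher cutoff (earlier k) stays
        if best is None or f1 > best.f1 + 1e-15:
            best = OperatingPoint(cutoff=float(s_sorted[k]), sensitivity=sens,
                                  specificity=spec, f1=f1)
    assert best is not None
    return best


def calibrate_precision(
    scores_by_class: dict[str, np.ndarray],
    labels_by_class: dict[str, np.ndarray],
) -> PrecisionCalibration:
    """Score -> precision calibration per class from held-out predictions.

    For every distinct observed score s, the precision among predictions
    with score >= s is recorded.  Classes without positives are marked
    unavailable (None).  Callers must pass out-of-fold predictions only;
    calibrating on training predictions would overstate precision.
    """
    table: dict[str, np.ndarray | None] = {}
    for klass, scores in scores_by_class.items():
        labels = np.asarray(labels_by_class[klass]).ravel().astype(int)
        scores = np.asarray(scores, dtype=float).ravel()
        if labels.sum() == 0:
            table[klass] = None
            continue
        order = np.argsort(-scores, kind="stable")
        s_sorted, l_sorted = scores[order], labels[order]
        tp = np.cumsum(l_sorted)
        n = np.arange(1, len(s_sorted) + 1)
        distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
        rows = np.column_stack(
            [s_sorted[distinct], tp[distinct] / n[distinct], n[distinct]]
        )
        table[klass] = rows[np.argsort(rows[:, 0])]
    return PrecisionCalibration(table=table)
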