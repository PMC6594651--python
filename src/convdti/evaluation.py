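"""Classification performance metrics.

Threshold metrics come from the confusion matrix (score >= threshold calls
positive): sensitivity TP/P, specificity TN/N, precision TP/(TP+FP), accuracy
(TP+TN)/(P+N). Two F1 variants are reported: the standard harmonic mean
2*Sen*Pre/(Sen+Pre) as the headline, and the halved variant Sen*Pre/(Sen+Pre)
kept for comparability with sources that print it that way. Ranking metrics
are threshold-free: AUC (trapezoidal area under the ROC curve, equal to the
normalised Mann-Whitney U statistic) and AUPR (step-wise area under the
precision-recall curve, i.e. average precision).

Undefined metrics (division by zero) are reported as absent (None), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class MetricSet:
    sen: float | None = None
    spe: float | None = None
    pre: float | None = None
    acc: float | None = None
    f1_standard: float | None = None
    f1_paper: float | None = None
    auc: float | None = None
    aupr: float | None = None
    reasons: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("sen", "spe", "pre", "acc", "f1_standard", "f1_paper", "auc", "aupr")}


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels.astype(int)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts at a threshold; score >= threshold calls positive."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    calls = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(calls & (labels == 1))),
        fp=int(np.sum(calls & (labels == 0))),
        tn=int(np.sum(~calls & (labels == 0))),
        fn=int(np.sum(~calls & (labels == 1))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from confusion counts; undefined ones are absent."""
    vals: dict[str, float | None] = {}
    reasons = []
    vals["sen"] = c.tp / c.p if c.p > 0 else None
    vals["spe"] = c.tn / c.n if c.n > 0 else None
    vals["pre"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    vals["acc"] = (c.tp + c.tn) / c.total if c.total > 0 else None
    if vals["sen"] is None:
        reasons.append("sensitivity undefined: no positive examples")
    if vals["spe"] is None:
        reasons.append("specificity undefined: no negative examples")
    if vals["pre"] is None:
        reasons.append("precision undefined: no positive calls")
    sen, pre = vals["sen"], vals["pre"]
    if sen is not None and pre is not None and (sen + pre) > 0:
        vals["f1_paper"] = sen * pre / (sen + pre)
        vals["f1_standard"] = 2 * vals["f1_paper"]
    else:
        vals["f1_paper"] = vals["f1_standard"] = None
        reasons.append("F1 undefined")
    return MetricSet(**vals, reasons=tuple(reasons))


def auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoidal; ties count one half)."""
    labels = _check_binary(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve by step-wise interpolation
    (average precision); invariant to strictly monotone score transforms."""
    labels = _check_binary(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUPR requires both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate_scores(scores, labels, threshold: float) -> MetricSet:
    """Full metric set: threshold metrics at ``threshold`` plus AUC/AUPR."""
    base = metrics(confusion(scores, labels, threshold))
    labels_arr = _check_binary(labels)
    two_class = len(set(labels_arr.tolist())) == 2
    return MetricSet(
        **{**base.as_dict(),
           "auc": auc(scores, labels) if two_class else None,
           "aupr": aupr(scores, labels) if two_class else None},
        reasons=base.reasons if two_class else base.reasons + ("AUC/AUPR undefined: single class",),
    )
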