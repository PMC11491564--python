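"""Class-imbalance loss weights and classifier performance metrics.

This module scores externally produced predictions (any classifier, any
channel configuration); it trains nothing.

Loss weights: for class c with n_c training samples out of N total,
``w_c = (N / n_c) ** lambda`` — inverse-frequency weighting raised to an
exponent.  lambda > 1 exaggerates the spread between minority and majority
classes; lambda < 1 flattens it; lambda = 1 is plain inverse frequency.

Metrics (per class, one-vs-rest, then macro-averaged): sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), precision Prec = TP/(TP+FP),
F1 = 2*Prec*SN/(Prec+SN), area under the ROC curve (AUC) and area under the
precision-recall curve (AUPRC).  Ratios with a zero denominator are
undefined (returned as None) and excluded from macro averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError, UndefinedValueError

METRIC_NAMES = ("SN", "SP", "Prec", "F1", "AUPRC", "AUC")


@dataclass(frozen=True)
class ClassCounts:
    """Per-class training-set sizes plus the weighting exponent lambda."""

    counts: Mapping[str, int]
    lambda_: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ContractError("need at least 2 classes")
        for c, n in self.counts.items():
            if not (isinstance(n, (int, np.integer)) and n >= 1):
                raise ContractError(f"count for class {c!r} must be a positive integer, got {n}")
        if not self.lambda_ > 0:
            raise ContractError(f"lambda must be > 0, got {self.lambda_}")


def class_weights(counts: ClassCounts) -> dict[str, float]:
    """Inverse-frequency loss weights w_c = (sum_i n_i / n_c) ** lambda.

    Strictly decreasing in n_c for every lambda > 0, so minority classes
    always weigh more.  Weights are not normalized; loss frameworks rescale
    freely.
    """
    total = sum(counts.counts.values())
    return {c: (total / n) ** counts.lambda_ for c, n in counts.counts.items()}


def confusion_metrics(
    y_true: Sequence, y_pred: Sequence, positive: object
) -> dict[str, float | None]:
    """SN, SP, Prec and F1 for one class treated one-vs-rest.

    A ratio whose denominator is zero (e.g. precision of an all-negative
    predictor) is returned as ``None`` and skipped by macro averaging.
    """
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ContractError(f"length mismatch: {t.shape} true vs {p.shape} predicted")
    if positive not in t and positive not in p:
        raise ContractError(f"positive class {positive!r} appears in neither labels nor predictions")
    tp = int(np.sum((t == positive) & (p == positive)))
    fn = int(np.sum((t == positive) & (p != positive)))
    fp = int(np.sum((t != positive) & (p == positive)))
    tn = int(np.sum((t != positive) & (p != positive)))

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    if prec is None or sn is None or prec + sn == 0:
        f1 = None if (prec is None or sn is None) else 0.0
    else:
        f1 = 2.0 * prec * sn / (prec + sn)
    return {"SN": sn, "SP": sp, "Prec": prec, "F1": f1}


def curve_metrics(
    y_true: Sequence, scores: Sequence[float], positive: object
) -> dict[str, float]:
    """AUC (rank statistic / trapezoidal ROC) and AUPRC (step integration).

    ``scores`` are continuous confidences for the positive class; both
    metrics need at least one positive and one negative sample.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    t = (np.asarray(y_true) == positive).astype(int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ContractError(f"length mismatch: {t.shape} true vs {s.shape} scores")
    if t.min() == t.max():
        raise UndefinedValueError(
            f"curve metrics undefined: labels are single-class w.r.t. {positive!r}"
        )
    return {
        "AUPRC": float(average_precision_score(t, s)),
        "AUC": float(roc_auc_score(t, s)),
    }


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class metric table plus macro averages."""

    per_class: Mapping[str, Mapping[str, float | None]]
    macro: Mapping[str, float | None]

    def as_dict(self) -> dict:
        return {"per_class": {c: dict(m) for c, m in self.per_class.items()},
                "macro": dict(self.macro)}


def macro_average(
    per_class: Mapping[str, Mapping[str, float | None]]
) -> dict[str, float | None]:
    """Unweighted mean of each metric over the classes where it is defined."""
    out: dict[str, float | None] = {}
    metric_keys: list[str] = []
    for m in per_class.values():
        for k in m:
            if k not in metric_keys:
                metric_keys.append(k)
    for k in metric_keys:
        vals = [m[k] for m in per_class.values() if m.get(k) is not None]
        out[k] = float(np.mean(vals)) if vals else None
    if all(v is None for v in out.values()):
        raise UndefinedValueError("macro average undefined: no class has any defined metric")
    return out


def evaluate_predictions(
    y_true: Sequence,
    y_pred: Sequence,
    scores: Mapping[str, Sequence[float]] | None = None,
    classes: Sequence | None = None,
) -> ClassMetrics:
    """Full per-class + macro metric table for a multiclass prediction set.

    ``scores``, if given, maps each class to its positive-class confidence
    per sample (enables AUC/AUPRC).
    """
    t = np.asarray(y_true)
    if classes is None:
        classes = sorted(set(t.tolist()))
    per: dict[str, dict[str, float | None]] = {}
    for c in classes:
        row = confusion_metrics(y_true, y_pred, c)
        if scores is not None and c in scores:
            try:
                row.update(curve_metrics(y_true, scores[c], c))
            except UndefinedValueError:
                row.update({"AUPRC": None, "AUC": None})
        per[str(c)] = row
    return ClassMetrics(per_class=per, macro=macro_average(per))
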