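"""One-vs-rest evaluation of predicted against annotated activity streams.

For each activity class the predicted/true label vectors are reduced to
one-vs-rest confusion counts (TP, FP, TN, FN), from which the five
standard screening statistics are derived:

    TPR = TP/(TP+FN)   sensitivity / recall
    TNR = TN/(TN+FP)   specificity
    PPV = TP/(TP+FP)   precision
    NPV = TN/(TN+FN)
    ACC = (TP+TN)/n

A zero denominator yields NaN (rendered "NA" in reports), never 0 and
never an exception.  ROC curves are threshold sweeps over the per-class
scores; the trapezoidal AUC equals the Mann-Whitney pairwise-concordance
statistic with half-credit for ties.

The default evaluation unit is the window.  An event-level mode is also
provided, pairing each annotated event with the predicted event stream
and requiring >= 50% temporal overlap for a match.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_core import ActivityClass, CLASS_ORDER, EventStream, ValidationError

__all__ = [
    "confusion_counts",
    "classification_stats",
    "roc_curve_auc",
    "event_level_labels",
    "stats_report",
]

COUNT_COLUMNS = ["TP", "FP", "TN", "FN"]
STAT_COLUMNS = ["TPR", "TNR", "PPV", "NPV", "ACC"]


def _as_values(labels: Sequence) -> np.ndarray:
    return np.array([ActivityClass(l).value for l in labels], dtype=object)


def confusion_counts(
    pred: Sequence,
    truth: Sequence,
    classes: Sequence[ActivityClass] = CLASS_ORDER,
) -> pd.DataFrame:
    """One-vs-rest TP/FP/TN/FN per class; every row sums to ``len(truth)``."""
    if len(pred) != len(truth):
        raise ValidationError(
            f"pred ({len(pred)}) and truth ({len(truth)}) lengths differ"
        )
    p = _as_values(pred)
    t = _as_values(truth)
    n = len(t)
    rows = {}
    for c in classes:
        cv = ActivityClass(c).value
        tp = int(np.sum((p == cv) & (t == cv)))
        fp = int(np.sum((p == cv) & (t != cv)))
        fn = int(np.sum((p != cv) & (t == cv)))
        rows[cv] = [tp, fp, n - tp - fp - fn, fn]
    return pd.DataFrame.from_dict(rows, orient="index", columns=COUNT_COLUMNS)


def classification_stats(counts: pd.DataFrame) -> pd.DataFrame:
    """TPR/TNR/PPV/NPV/ACC per class from one-vs-rest counts.

    Zero denominators produce NaN markers, not exceptions.
    """
    tp = counts["TP"].to_numpy(dtype=float)
    fp = counts["FP"].to_numpy(dtype=float)
    tn = counts["TN"].to_numpy(dtype=float)
    fn = counts["FN"].to_numpy(dtype=float)

    def ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    return pd.DataFrame(
        {
            "TPR": ratio(tp, tp + fn),
            "TNR": ratio(tn, tn + fp),
            "PPV": ratio(tp, tp + fp),
            "NPV": ratio(tn, tn + fn),
            "ACC": ratio(tp + tn, tp + fp + tn + fn),
        },
        index=counts.index,
    )


def roc_curve_auc(
    scores: Sequence[float], truth_binary: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC threshold sweep and trapezoidal AUC for one class's scores.

    Returns ``(fpr, tpr, auc)``.  The AUC equals the Mann-Whitney U
    statistic divided by ``n_pos * n_neg`` (ties get half credit).
    Raises :class:`ValidationError` unless both outcome classes occur.
    """
    y = np.asarray(truth_binary, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size:
        raise ValidationError("scores and truth lengths differ")
    if len(np.unique(y)) < 2:
        raise ValidationError("ROC needs at least one positive and one negative unit")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def event_level_labels(
    pred: EventStream,
    truth: EventStream,
    min_overlap: float = 0.5,
) -> tuple[list[ActivityClass], list[ActivityClass]]:
    """Pair each annotated event with the dominant predicted label.

    For every truth event, the predicted class covering the largest share
    of it is taken; if that share is below ``min_overlap`` the pair is
    counted as a disagreement using the dominant class anyway (the event
    was not matched).  Returns aligned (pred, truth) label lists, one per
    annotated event.
    """
    pred_labels, truth_labels = [], []
    for ev in truth:
        cover = {c: 0.0 for c in CLASS_ORDER}
        for pe in pred:
            ov = min(ev.end, pe.end) - max(ev.start, pe.start)
            if ov > 0:
                cover[pe.label] += ov
        dominant = max(CLASS_ORDER, key=lambda c: cover[c])
        pred_labels.append(dominant)
        truth_labels.append(ev.label)
    return pred_labels, truth_labels


def stats_report(pred: Sequence, truth: Sequence) -> dict:
    """JSON-ready per-class counts + statistics (NaN rendered as "NA")."""
    counts = confusion_counts(pred, truth)
    stats = classification_stats(counts)
    out = {}
    for cls in counts.index:
        row = {c: int(counts.loc[cls, c]) for c in COUNT_COLUMNS}
        for c in STAT_COLUMNS:
            v = stats.loc[cls, c]
            row[c] = "NA" if pd.isna(v) else float(v)
        out[cls] = row
    return out
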