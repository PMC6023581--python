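"""Confusion matrices and per-class classification metrics at the 5-s level.

Sensitivity, specificity and balanced accuracy (the mean of sensitivity and
specificity) are computed per posture class using the one-vs-rest collapse
of the 5x5 confusion matrix, per participant, then averaged unweighted over
participants.  Classes absent from a participant's ground truth are
undefined (NaN) for that participant and excluded from the average.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .core import CLASS_NAMES

__all__ = [
    "confusion_matrix",
    "per_class_metrics",
    "average_over_participants",
    "write_metrics",
    "write_confusion_matrix",
]

_N = len(CLASS_NAMES)

METRIC_COLUMNS = ("sensitivity", "specificity", "balanced_accuracy")


def confusion_matrix(truth, pred) -> np.ndarray:
    """5x5 count matrix; rows are truth, columns are prediction."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction must have equal length")
    if truth.size == 0:
        raise ValueError("empty label sequences")
    return _sk_confusion(truth, pred, labels=list(range(_N))).astype(np.int64)


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """Sensitivity, specificity and balanced accuracy per class.

    Specificity uses the one-vs-rest collapse: TN / (TN + FP) where the
    negative class is every other posture.  Classes with no truth windows
    (zero row sum) get NaN for all three metrics.
    """
    cm = np.asarray(cm)
    if cm.shape != (_N, _N) or np.any(cm < 0):
        raise ValueError("confusion matrix must be 5x5 with non-negative counts")
    total = cm.sum()
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    diag = np.diag(cm)

    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, diag / row, np.nan)
        fp = col - diag
        tn = total - row - fp
        spec = np.where((tn + fp) > 0, tn / (tn + fp), np.nan)
    spec = np.where(row > 0, spec, np.nan)  # undefined classes stay undefined
    bal = (sens + spec) / 2.0
    return pd.DataFrame(
        {"sensitivity": sens, "specificity": spec, "balanced_accuracy": bal},
        index=list(CLASS_NAMES),
    )


def average_over_participants(per_participant: list[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean over participants with defined metrics.

    Adds an ``n_participants`` column counting contributors per class.
    """
    if not per_participant:
        raise ValueError("no participants")
    stacked = np.stack([df[list(METRIC_COLUMNS)].to_numpy() for df in per_participant])
    with warnings.catch_warnings():
        # a class undefined for every participant is a legitimate all-NaN slice
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    n = np.sum(~np.isnan(stacked[:, :, 0]), axis=0)
    out = pd.DataFrame(mean, columns=list(METRIC_COLUMNS), index=list(CLASS_NAMES))
    out["n_participants"] = n
    return out


def write_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="class", float_format="%.6f")


def write_confusion_matrix(cm: np.ndarray, path) -> None:
    pd.DataFrame(cm, index=list(CLASS_NAMES), columns=list(CLASS_NAMES)).to_csv(
        path, index_label="truth\\pred"
    )
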