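"""Random-forest posture classification with leave-one-participant-out CV.

The forest is an ensemble of 500 decision trees; each tree is grown on a
bootstrap sample of the training windows and a fixed random subset of 15%
of the 41 features (6 features), i.e. feature subsampling is per tree, not
per split.  Window probabilities are the average of the per-tree class
probabilities.

Training uses only *pure* 5-s windows (all five constituent seconds share
one posture class); testing includes all windows, with impure windows given
a majority ground-truth label (ties favour a transition class present in
the window, then the fixed class order).  Because the derived transition
labels last exactly one second, no 5-s window is ever purely a transition
class: the forest therefore never trains on (and never predicts) the two
transition classes, which is flagged per fold in the results.

Cross-validation is leave-one-participant-out: each participant in turn is
the test subject, with every other participant's pure windows forming the
training set, so no within-person information leaks into a test fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .core import CLASS_NAMES, PostureClass, SecondLabelSeries
from .evaluation import confusion_matrix, per_class_metrics, average_over_participants
from .features import FEATURE_NAMES, N_FEATURES
from .transition_filter import apply_time_filter

__all__ = [
    "ForestConfig",
    "WindowLabel",
    "PostureModel",
    "ParticipantWindows",
    "UNLABELED",
    "label_windows",
    "window_labels_from_seconds",
    "train_forest",
    "predict_proba",
    "lopo_cross_validate",
    "audit_leakage",
    "save_model",
    "load_model",
    "LopoResult",
    "FoldResult",
]

UNLABELED = -1  # sentinel for windows outside the labeled/worn span

_TRANSITIONS = (int(PostureClass.SIT_TO_STAND), int(PostureClass.STAND_TO_SIT))


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of the posture forest.

    ``feature_fraction`` of the 41 features, rounded to the nearest integer
    (6 by default), are drawn per tree without replacement; each tree's
    training sample is a bootstrap (with replacement) of
    ``bootstrap_fraction`` of the windows.  Tree growing uses Gini impurity
    and a minimum leaf of one sample.

    ``max_depth`` bounds tree depth (default 16).  Trees whose feature
    subset carries no class signal otherwise memorise sampling noise to
    depths of 50+, which multiplies training cost without changing the
    averaged ensemble prediction; depth 16 (over 65 000 potential leaves)
    far exceeds the structure 41 features can express.  Set ``None`` to
    grow unbounded trees.
    """

    n_trees: int = 500
    feature_fraction: float = 0.15
    bootstrap_fraction: float = 1.0
    max_depth: int | None = 16
    min_samples_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")

    @property
    def features_per_tree(self) -> int:
        return int(round(self.feature_fraction * N_FEATURES))


@dataclass(frozen=True)
class WindowLabel:
    """Ground-truth assignment for one 5-s window."""

    window_index: int
    label: int  # PostureClass value, or UNLABELED
    pure: bool  # all five constituent seconds share one class


def _majority_label(seconds: np.ndarray) -> int:
    """Majority class of a 5-tuple of second labels.

    Ties favour a transition class present anywhere in the window (the two
    transitions themselves ordered SIT_TO_STAND first), then the fixed class
    order SIT < STAND < STEP.
    """
    counts = np.bincount(seconds, minlength=5)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return int(tied[0])
    present_transitions = [t for t in _TRANSITIONS if counts[t] > 0]
    if present_transitions:
        return present_transitions[0]
    return int(tied[0])


def label_windows(
    seconds: SecondLabelSeries,
    windows,
    window_s: float = 5.0,
) -> list[WindowLabel]:
    """Assign a ground-truth label and purity flag to each window.

    ``windows`` may be a sequence of feature windows or an integer count;
    window *i* covers seconds ``[i*window_s, (i+1)*window_s)`` from the
    label series start.  Windows extending past the labeled span, or
    containing non-wear (excluded) seconds, are UNLABELED.
    """
    n_windows = windows if isinstance(windows, int) else len(windows)
    w = int(round(window_s))
    labels = seconds.labels
    excluded = seconds.excluded
    out: list[WindowLabel] = []
    for i in range(n_windows):
        lo, hi = i * w, (i + 1) * w
        if hi > len(labels) or np.any(excluded[lo:hi]):
            out.append(WindowLabel(i, UNLABELED, False))
            continue
        sec = labels[lo:hi].astype(np.int64)
        pure = bool(np.all(sec == sec[0]))
        lab = int(sec[0]) if pure else _majority_label(sec)
        out.append(WindowLabel(i, lab, pure))
    return out


def window_labels_from_seconds(
    seconds: SecondLabelSeries, n_windows: int, window_s: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Vector form of :func:`label_windows`: (labels, pure) arrays."""
    wl = label_windows(seconds, n_windows, window_s)
    return (
        np.array([w.label for w in wl], dtype=np.int64),
        np.array([w.pure for w in wl], dtype=bool),
    )


@dataclass
class PostureModel:
    """A trained posture forest plus everything needed to reproduce it."""

    bagging: BaggingClassifier
    config: ForestConfig
    feature_names: tuple[str, ...]
    classes_present: np.ndarray  # PostureClass values seen in training
    degenerate: bool  # single-class training set

    @property
    def n_trees(self) -> int:
        return len(self.bagging.estimators_)


def _feature_array(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns {missing[:3]}")
        return features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must have {N_FEATURES} columns")
    return arr


def train_forest(features, labels, config: ForestConfig | None = None) -> PostureModel:
    """Train the posture forest on pure, labeled windows."""
    config = config or ForestConfig()
    X = _feature_array(features)
    y = np.asarray(labels, dtype=np.int64)
    if X.shape[0] != y.size:
        raise ValueError("features and labels must align")
    if y.size == 0:
        raise ValueError("empty training set")
    if np.any(y == UNLABELED):
        raise ValueError("training labels must not contain UNLABELED windows")

    classes_present = np.unique(y)
    bagging = BaggingClassifier(
        estimator=DecisionTreeClassifier(
            criterion="gini",
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
        ),
        n_estimators=config.n_trees,
        max_samples=config.bootstrap_fraction,
        max_features=config.features_per_tree,
        bootstrap=True,
        bootstrap_features=False,
        random_state=config.seed,
        n_jobs=None,
    )
    bagging.fit(X, y)
    return PostureModel(
        bagging=bagging,
        config=config,
        feature_names=tuple(FEATURE_NAMES),
        classes_present=classes_present,
        degenerate=classes_present.size < 2,
    )


def predict_proba(model: PostureModel, features) -> np.ndarray:
    """Per-window five-class probabilities, averaged over trees.

    Classes absent from the training set always receive probability 0.
    """
    X = _feature_array(features)
    p_trained = model.bagging.predict_proba(X)
    probs = np.zeros((X.shape[0], len(CLASS_NAMES)))
    probs[:, model.bagging.classes_.astype(int)] = p_trained
    return probs


def save_model(model: PostureModel, path) -> None:
    """Serialise a model to one self-describing file (config, seed, orders)."""
    payload = {
        "format": "hipposture-posture-model",
        "config": model.config,
        "feature_names": model.feature_names,
        "class_names": CLASS_NAMES,
        "classes_present": model.classes_present,
        "degenerate": model.degenerate,
        "bagging": model.bagging,
    }
    joblib.dump(payload, path)


def load_model(path) -> PostureModel:
    payload = joblib.load(path)
    if payload.get("format") != "hipposture-posture-model":
        raise ValueError("not a posture model file")
    return PostureModel(
        bagging=payload["bagging"],
        config=payload["config"],
        feature_names=tuple(payload["feature_names"]),
        classes_present=payload["classes_present"],
        degenerate=payload["degenerate"],
    )


@dataclass
class ParticipantWindows:
    """One participant's windows, ready for cross-validation."""

    participant_id: str
    features: pd.DataFrame  # includes the 41 canonical feature columns
    labels: np.ndarray  # ground-truth window labels (UNLABELED allowed)
    pure: np.ndarray  # purity flags

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.pure = np.asarray(self.pure, dtype=bool)
        n = len(self.features)
        if self.labels.size != n or self.pure.size != n:
            raise ValueError("labels/pure must align with features")


@dataclass
class FoldResult:
    participant_id: str
    train_participants: tuple[str, ...]
    probs: np.ndarray  # (n_windows, 5)
    predicted: np.ndarray  # filtered labels
    truth: np.ndarray  # ground-truth labels (UNLABELED excluded from scoring)
    trained_classes: tuple[int, ...]
    metrics: pd.DataFrame  # per-class metrics with `in_training` flag


@dataclass
class LopoResult:
    folds: dict[str, FoldResult]
    averaged: pd.DataFrame
    pooled_confusion: np.ndarray


def lopo_cross_validate(
    cohort: list[ParticipantWindows],
    config: ForestConfig | None = None,
    time_filter: bool = True,
) -> LopoResult:
    """Leave-one-participant-out cross-validation over a cohort.

    For each participant, a forest is trained on the pure windows of all
    *other* participants and applied to all of the held-out participant's
    windows; predictions are decoded through the two-pass transition filter
    (unless ``time_filter=False``) and scored against the majority
    ground-truth labels.  Metrics are computed per participant and averaged
    unweighted; the confusion matrix is pooled over folds.

    Classes absent from a fold's training set are flagged via the
    ``in_training`` metrics column; their metrics remain defined whenever
    the class occurs in the fold's test truth.
    """
    config = config or ForestConfig()
    if len(cohort) < 2:
        raise ValueError("need at least 2 participants")
    ids = [p.participant_id for p in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids")

    folds: dict[str, FoldResult] = {}
    pooled = np.zeros((5, 5), dtype=np.int64)
    per_participant_metrics = []
    for held_out in cohort:
        train = [p for p in cohort if p.participant_id != held_out.participant_id]
        X_parts, y_parts = [], []
        for p in train:
            keep = p.pure & (p.labels != UNLABELED)
            X_parts.append(_feature_array(p.features)[keep])
            y_parts.append(p.labels[keep])
        X_train = np.concatenate(X_parts)
        y_train = np.concatenate(y_parts)
        model = train_forest(X_train, y_train, config)

        probs = predict_proba(model, held_out.features)
        if time_filter:
            predicted = apply_time_filter(probs).labels.astype(np.int64)
        else:
            predicted = np.argmax(probs, axis=1).astype(np.int64)

        scored = held_out.labels != UNLABELED
        cm = confusion_matrix(held_out.labels[scored], predicted[scored])
        pooled += cm
        metrics = per_class_metrics(cm)
        trained = tuple(int(c) for c in model.classes_present)
        metrics["in_training"] = [c in trained for c in range(5)]
        per_participant_metrics.append(metrics)

        folds[held_out.participant_id] = FoldResult(
            participant_id=held_out.participant_id,
            train_participants=tuple(p.participant_id for p in train),
            probs=probs,
            predicted=predicted,
            truth=held_out.labels,
            trained_classes=trained,
            metrics=metrics,
        )

    averaged = average_over_participants(per_participant_metrics)
    return LopoResult(folds=folds, averaged=averaged, pooled_confusion=pooled)


def audit_leakage(result: LopoResult) -> int:
    """Number of folds whose training set contains the test participant (0 = clean)."""
    leaks = 0
    for pid, fold in result.folds.items():
        if pid in fold.train_participants:
            leaks += 1
    return leaks
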