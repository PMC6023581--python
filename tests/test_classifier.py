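"""Window labeling, forest training/prediction, LOPO protocol."""

import numpy as np
import pandas as pd
import pytest

from hipposture.classifier import (
    UNLABELED,
    ForestConfig,
    ParticipantWindows,
    audit_leakage,
    label_windows,
    load_model,
    lopo_cross_validate,
    predict_proba,
    save_model,
    train_forest,
)
from hipposture.core import SecondLabelSeries
from hipposture.features import FEATURE_NAMES, N_FEATURES

SIT, STAND, STEP, S2S, ST2S = range(5)
T0 = pd.Timestamp("2024-03-04T08:00:00")


def seconds(labels, excluded=None):
    return SecondLabelSeries(start_time=T0, labels=np.array(labels), excluded=excluded)


def toy_features(rng, means, n_per_class, noise=0.01):
    """Separable synthetic feature matrices.

    The canonical 'mean' feature carries the class signal (value means[k]
    with Gaussian noise sd 0.01); the remaining 40 features are constant, so
    trees whose feature subset misses the informative one carry no signal.
    """
    X_parts, y_parts = [], []
    for cls, mu in means.items():
        X = np.zeros((n_per_class, N_FEATURES))
        X[:, 0] = mu + rng.normal(0, noise, size=n_per_class)
        X_parts.append(X)
        y_parts.append(np.full(n_per_class, cls))
    return np.concatenate(X_parts), np.concatenate(y_parts)


class TestForestConfig:
    def test_defaults(self):
        cfg = ForestConfig()
        assert cfg.n_trees == 500
        assert cfg.feature_fraction == 0.15
        assert cfg.features_per_tree == 6  # round(0.15 * 41)

    def test_invalid(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=0)
        with pytest.raises(ValueError):
            ForestConfig(feature_fraction=1.5)


class TestLabelWindows:
    def test_unanimous_window_is_pure(self):
        wl = label_windows(seconds([SIT] * 5), 1)
        assert wl[0].pure and wl[0].label == SIT

    def test_tie_favours_present_transition(self):
        # SIT(2) vs STAND(2) tie with one transition second -> transition label
        wl = label_windows(seconds([SIT, SIT, S2S, STAND, STAND]), 1)
        assert not wl[0].pure
        assert wl[0].label == S2S

    def test_strict_majority(self):
        wl = label_windows(seconds([STAND] * 3 + [STEP] * 2), 1)
        assert not wl[0].pure
        assert wl[0].label == STAND

    def test_majority_beats_lone_transition(self):
        wl = label_windows(seconds([SIT, SIT, SIT, S2S, STAND]), 1)
        assert wl[0].label == SIT

    def test_window_outside_span_unlabeled(self):
        wl = label_windows(seconds([SIT] * 7), 2)
        assert wl[0].label == SIT
        assert wl[1].label == UNLABELED

    def test_nonwear_seconds_unlabel_window(self):
        excl = np.zeros(10, dtype=bool)
        excl[7] = True
        wl = label_windows(seconds([SIT] * 10, excl), 2)
        assert wl[0].label == SIT
        assert wl[1].label == UNLABELED


class TestTrainPredict:
    def test_single_class_degenerate(self, rng):
        X, y = toy_features(rng, {SIT: 1.0}, 30)
        model = train_forest(X, y, ForestConfig(n_trees=10, seed=0))
        assert model.degenerate
        probs = predict_proba(model, rng.normal(size=(5, N_FEATURES)))
        np.testing.assert_allclose(probs[:, SIT], 1.0)
        np.testing.assert_allclose(probs[:, 1:], 0.0)

    def test_separable_two_class_recovery(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STAND: 2.0}, 100)
        model = train_forest(X, y, ForestConfig(n_trees=100, seed=1))
        X_test, y_test = toy_features(rng, {SIT: 1.0, STAND: 2.0}, 50)
        pred = np.argmax(predict_proba(model, X_test), axis=1)
        oracle = np.where(X_test[:, 0] < 1.5, SIT, STAND)  # threshold oracle
        np.testing.assert_array_equal(oracle, y_test)
        assert np.mean(pred == oracle) >= 0.99

    def test_seed_determinism(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STEP: 2.0}, 40)
        X_test = rng.normal(1.5, 0.5, size=(30, N_FEATURES))
        p1 = predict_proba(train_forest(X, y, ForestConfig(n_trees=25, seed=7)), X_test)
        p2 = predict_proba(train_forest(X, y, ForestConfig(n_trees=25, seed=7)), X_test)
        np.testing.assert_array_equal(p1, p2)

    def test_different_seeds_same_argmax_on_separable(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STAND: 3.0}, 80)
        X_test, _ = toy_features(rng, {SIT: 1.0, STAND: 3.0}, 100)
        a = np.argmax(predict_proba(train_forest(X, y, ForestConfig(50, seed=1)), X_test), axis=1)
        b = np.argmax(predict_proba(train_forest(X, y, ForestConfig(50, seed=2)), X_test), axis=1)
        assert np.mean(a == b) >= 0.99

    def test_probabilities_sum_to_one(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STAND: 2.0, STEP: 3.0}, 30)
        model = train_forest(X, y, ForestConfig(n_trees=20, seed=3))
        probs = predict_proba(model, rng.normal(size=(50, N_FEATURES)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_features_per_tree_is_six(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STAND: 2.0}, 30)
        model = train_forest(X, y, ForestConfig(n_trees=15, seed=0))
        for feats in model.bagging.estimators_features_:
            assert len(feats) == 6

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_forest(np.empty((0, N_FEATURES)), np.empty(0))

    def test_column_mismatch_rejected(self, rng):
        X, y = toy_features(rng, {SIT: 1.0, STAND: 2.0}, 10)
        model = train_forest(X, y, ForestConfig(n_trees=5, seed=0))
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, 7)))

    def test_model_round_trip(self, rng, tmp_path):
        X, y = toy_features(rng, {SIT: 1.0, STEP: 2.0}, 30)
        model = train_forest(X, y, ForestConfig(n_trees=10, seed=5))
        save_model(model, tmp_path / "model.joblib")
        back = load_model(tmp_path / "model.joblib")
        X_test = rng.normal(size=(20, N_FEATURES))
        np.testing.assert_array_equal(
            predict_proba(model, X_test), predict_proba(back, X_test)
        )
        assert back.config == model.config


def make_participant(pid, rng, means, n=60):
    X, y = toy_features(rng, means, n)
    perm = rng.permutation(len(y))
    df = pd.DataFrame(X[perm], columns=list(FEATURE_NAMES))
    return ParticipantWindows(
        participant_id=pid, features=df, labels=y[perm], pure=np.ones(len(y), bool)
    )


class TestLopo:
    def test_identical_separable_participants_perfect(self, rng):
        means = {SIT: 1.0, STAND: 2.0}
        cohort = [make_participant(p, rng, means) for p in ("A", "B")]
        result = lopo_cross_validate(cohort, ForestConfig(n_trees=30, seed=0))
        for cls in ("SIT", "STAND"):
            assert result.averaged.loc[cls, "balanced_accuracy"] == pytest.approx(1.0)

    def test_leakage_audit_zero(self, rng):
        cohort = [
            make_participant(p, rng, {SIT: 1.0, STEP: 2.0}) for p in ("A", "B", "C")
        ]
        result = lopo_cross_validate(cohort, ForestConfig(n_trees=10, seed=0))
        assert audit_leakage(result) == 0
        for pid, fold in result.folds.items():
            assert pid not in fold.train_participants
            assert len(fold.train_participants) == 2

    def test_missing_class_flagged_per_fold(self, rng):
        # only participant C carries STEP truth; folds testing A/B train with STEP,
        # the fold testing C must train without it and be flagged
        cohort = [
            make_participant("A", rng, {SIT: 1.0, STAND: 2.0}),
            make_participant("B", rng, {SIT: 1.0, STAND: 2.0}),
            make_participant("C", rng, {SIT: 1.0, STEP: 3.0}),
        ]
        result = lopo_cross_validate(cohort, ForestConfig(n_trees=10, seed=0))
        fold_c = result.folds["C"]
        assert STEP not in fold_c.trained_classes
        assert not fold_c.metrics.loc["STEP", "in_training"]
        assert fold_c.metrics.loc["STEP", "sensitivity"] == 0.0

    def test_requires_two_participants(self, rng):
        with pytest.raises(ValueError):
            lopo_cross_validate([make_participant("A", rng, {SIT: 1.0, STAND: 2.0})])

    def test_pooled_confusion_conserves_scored_windows(self, rng):
        cohort = [
            make_participant(p, rng, {SIT: 1.0, STAND: 2.0}, n=40) for p in ("A", "B")
        ]
        result = lopo_cross_validate(cohort, ForestConfig(n_trees=10, seed=0))
        scored = sum(np.sum(p.labels != UNLABELED) for p in cohort)
        assert result.pooled_confusion.sum() == scored
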