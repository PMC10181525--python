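"""Metric identities, training protocol, and reference baselines."""

import numpy as np
import pytest

from leaffuse.evaluation import (TrainConfig, baseline_classifiers,
                                 compare_pipelines, evaluate,
                                 evaluate_predictions, train_head)
from leaffuse.heads import HeadConfig, build_head


def _from_confusion(C):
    """Expand a confusion matrix into (y_true, y_pred) pairs."""
    yt, yp = [], []
    for i, row in enumerate(C):
        for j, n in enumerate(row):
            yt += [i] * n
            yp += [j] * n
    return np.array(yt), np.array(yp)


def test_binary_confusion_metric_identities():
    yt, yp = _from_confusion([[8, 2], [3, 7]])
    rep = evaluate_predictions(yt, yp)
    assert rep.precision[0] == pytest.approx(100 * 8 / 11, abs=0.01)  # 72.73
    assert rep.recall[0] == pytest.approx(80.0)
    assert rep.f1[0] == pytest.approx(76.19, abs=0.01)
    assert rep.accuracy == pytest.approx(75.0)
    np.testing.assert_array_equal(rep.confusion, [[8, 2], [3, 7]])


def test_perfect_predictor_scores_100_everywhere():
    y = np.repeat(np.arange(6), 4)
    rep = evaluate_predictions(y, y)
    assert rep.accuracy == 100.0
    assert rep.ap == 100.0
    np.testing.assert_allclose(rep.precision, 100.0)
    np.testing.assert_allclose(rep.recall, 100.0)
    np.testing.assert_allclose(rep.f1, 100.0)


def test_constant_predictor_on_balanced_binary_data():
    y = np.array([0] * 10 + [1] * 10)
    rep = evaluate_predictions(y, np.zeros(20, dtype=int), n_classes=2)
    assert rep.accuracy == 50.0
    assert rep.recall[1] == 0.0


def test_f1_recomputes_from_reported_p_and_r():
    rng = np.random.default_rng(0)
    yt = rng.integers(0, 4, 200)
    yp = rng.integers(0, 4, 200)
    rep = evaluate_predictions(yt, yp)
    for c in range(4):
        p, r = rep.precision[c], rep.recall[c]
        expected = 2 * p * r / (p + r) if p + r > 0 else 0.0
        assert rep.f1[c] == pytest.approx(expected, abs=1e-9)


def test_confusion_matrix_conservation():
    rng = np.random.default_rng(1)
    yt = rng.integers(0, 5, 300)
    yp = rng.integers(0, 5, 300)
    rep = evaluate_predictions(yt, yp)
    assert rep.confusion.sum() == 300
    for c in range(5):
        assert rep.confusion[c].sum() == (yt == c).sum()


def test_ap_is_macro_precision_and_literal_sum_mode_retained():
    yt, yp = _from_confusion([[8, 2], [3, 7]])
    rep = evaluate_predictions(yt, yp)
    assert rep.ap == pytest.approx(rep.precision.mean())
    assert rep.ap_literal_sum == pytest.approx(rep.precision.sum() / 100.0)


def test_auc_bounds_and_perfect_separation():
    y = np.array([0, 0, 1, 1])
    scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    rep = evaluate_predictions(y, scores.argmax(axis=1), scores=scores)
    np.testing.assert_allclose(rep.auc, 1.0)
    rng = np.random.default_rng(2)
    noisy = rng.uniform(size=(50, 2))
    rep2 = evaluate_predictions(rng.integers(0, 2, 50),
                                noisy.argmax(axis=1), scores=noisy)
    assert np.all((rep2.auc >= 0) & (rep2.auc <= 1))


def test_absent_class_warns_and_is_excluded_from_macro():
    y = np.array([0, 0, 1, 1])
    with pytest.warns(UserWarning, match="absent"):
        rep = evaluate_predictions(y, y, n_classes=3)
    assert rep.ap == 100.0  # class 2 excluded


# -- training protocol --------------------------------------------------------

def test_zero_epochs_returns_model_unchanged(separable_features):
    X, y, _ = separable_features
    cfg = HeadConfig("F", input_dim=16, n_classes=2, hidden_dim=8, seed=0)
    model = build_head(cfg)
    before = [p.data.copy() for p in model.parameters()]
    model, hist = train_head(model, X, y, config=TrainConfig(epochs=0))
    for p, b in zip(model.parameters(), before):
        np.testing.assert_array_equal(p.data, b)
    assert hist["train_loss"] == []


def test_constant_lr_schedule_is_identity_of_switch(separable_features):
    X, y, _ = separable_features
    cfg = TrainConfig(lr_initial=1e-3, lr_final=1e-3, lr_switch_epoch=2,
                      epochs=4, seed=3)
    m1 = build_head(HeadConfig("F", 16, 2, hidden_dim=8, seed=1))
    m2 = build_head(HeadConfig("F", 16, 2, hidden_dim=8, seed=1))
    _, h1 = train_head(m1, X[:40], y[:40], config=cfg)
    # moving the switch epoch changes nothing when both rates are equal
    cfg2 = TrainConfig(lr_initial=1e-3, lr_final=1e-3, lr_switch_epoch=99,
                       epochs=4, seed=3)
    _, h2 = train_head(m2, X[:40], y[:40], config=cfg2)
    assert h1["train_loss"] == h2["train_loss"]


def test_training_reduces_loss_and_is_seed_deterministic(cluster_data):
    _, shallow, depth, y, split = cluster_data
    X = np.concatenate([shallow, depth], axis=1)
    cfg = TrainConfig(epochs=10, seed=4, lr_switch_epoch=5)
    m1 = build_head(HeadConfig("F", X.shape[1], 6, hidden_dim=32, seed=5))
    m2 = build_head(HeadConfig("F", X.shape[1], 6, hidden_dim=32, seed=5))
    _, h1 = train_head(m1, X, y, split=split, config=cfg)
    _, h2 = train_head(m2, X, y, split=split, config=cfg)
    assert h1["train_loss"][-1] < h1["train_loss"][0]
    assert h1["train_loss"] == h2["train_loss"]
    assert len(h1["val_loss"]) == 10


def test_out_of_range_label_rejected(separable_features):
    X, y, _ = separable_features
    model = build_head(HeadConfig("F", 16, 2, hidden_dim=8, seed=0))
    with pytest.raises(ValueError, match="label"):
        train_head(model, X[:8], np.full(8, 9), config=TrainConfig(epochs=1))


# -- baselines ----------------------------------------------------------------

@pytest.mark.parametrize("which", ["svm", "random_forest"])
def test_baselines_solve_separable_clusters(which, separable_features):
    X, y, split = separable_features
    rep = baseline_classifiers(X, y, split, which, seed=0)
    assert rep.accuracy >= 95.0


def test_baselines_near_chance_on_random_labels():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(120, 16))
    y = rng.integers(0, 6, 120)
    from leaffuse.synthetic import stratified_split
    split = stratified_split(y, seed=8)
    for which in ("svm", "random_forest"):
        rep = baseline_classifiers(X, y, split, which, seed=9)
        assert 0.0 <= rep.accuracy <= 35.0


def test_depth_one_forest_cannot_represent_xor():
    rng = np.random.default_rng(10)
    X = rng.uniform(-1, 1, size=(400, 2))
    y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
    X2, y2 = np.concatenate([X, X]), np.concatenate([y, y])
    split = np.array(["train"] * 400 + ["test"] * 400)  # test == train set
    rep = baseline_classifiers(
        X2, y2, split, "random_forest", seed=11,
        params={"max_depth": 1, "n_estimators": 20, "max_features": 2})
    assert rep.accuracy <= 75.0


def test_unknown_baseline_rejected(separable_features):
    X, y, split = separable_features
    with pytest.raises(ValueError):
        baseline_classifiers(X, y, split, "knn")


# -- comparison table ---------------------------------------------------------

def test_compare_pipelines_rows_and_identical_arms(cluster_data):
    _, shallow, depth, y, split = cluster_data
    cfg = TrainConfig(epochs=5, seed=12, lr_switch_epoch=3)
    df = compare_pipelines({"a": shallow, "b": shallow}, y, split,
                           head_types=("F",), config=cfg,
                           head_kwargs={"hidden_dim": 32})
    assert len(df) == 2
    a = df[df.source == "a"].iloc[0]
    b = df[df.source == "b"].iloc[0]
    for col in ("accuracy", "precision", "recall", "f1", "ap"):
        assert a[col] == b[col]
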