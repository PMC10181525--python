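"""Attention primitives and the three classification heads."""

import numpy as np
import pytest

from leaffuse.autodiff import Tensor, cross_entropy
from leaffuse.heads import (AttentionParams, FANet, HeadConfig,
                            MultiHeadAttention, build_head,
                            multi_head_attention, predict_proba,
                            scaled_dot_product_attention)
from leaffuse.nn import Adam


# -- scaled dot-product attention ---------------------------------------------

def test_single_token_attention_returns_value_unchanged():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(1, 5))
    out, w = scaled_dot_product_attention(rng.normal(size=(1, 4)),
                                          rng.normal(size=(1, 4)), v)
    np.testing.assert_allclose(out, v)
    np.testing.assert_allclose(w, [[1.0]])


def test_zero_query_gives_uniform_weights_and_column_mean():
    rng = np.random.default_rng(1)
    K, V = rng.normal(size=(6, 4)), rng.normal(size=(6, 3))
    out, w = scaled_dot_product_attention(np.zeros((2, 4)), K, V)
    np.testing.assert_allclose(w, np.full((2, 6), 1 / 6))
    np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (2, 1)))


def test_strongly_peaked_scores_select_matching_values():
    """Logit gap 10 -> softmax weight 1/(1+e^-10) ~ 0.9999546."""
    Dk = 4
    Q = np.eye(2, Dk) * 10 * np.sqrt(Dk)
    K = np.eye(2, Dk)
    V = np.array([[1.0, 0.0], [0.0, 1.0]])
    out, w = scaled_dot_product_attention(Q, K, V, Dk=Dk)
    np.testing.assert_allclose(np.diag(w), 1 / (1 + np.exp(-10.0)), atol=1e-9)
    np.testing.assert_allclose(out, V, atol=1e-4)


def test_attention_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((2, 4)),
                                     np.zeros((2, 4)))
    with pytest.raises(ValueError):
        scaled_dot_product_attention(np.zeros((2, 3)), np.zeros((4, 3)),
                                     np.zeros((5, 2)))


# -- multi-head attention -----------------------------------------------------

def test_identity_projections_single_head_pass_token_through():
    d = 4
    params = AttentionParams(np.eye(d), np.eye(d), np.eye(d), np.eye(d),
                             h=1, Dk=d)
    x = np.array([[0.3, -1.2, 0.8, 0.1]])
    np.testing.assert_allclose(multi_head_attention(x, params), x)


def test_batched_layer_matches_naive_per_head_loop():
    rng = np.random.default_rng(2)
    layer = MultiHeadAttention(16, 4, rng)
    X = rng.normal(size=(3, 7, 16))
    batched = layer(Tensor(X)).data
    params = layer.export_params()
    naive = np.stack([multi_head_attention(X[b], params) for b in range(3)])
    assert np.abs(batched - naive).max() < 1e-6


def test_attention_weight_rows_sum_to_one_every_head():
    rng = np.random.default_rng(3)
    for h in (1, 2, 4):
        params = AttentionParams(rng.normal(size=(8, 8)), rng.normal(size=(8, 8)),
                                 rng.normal(size=(8, 8)), rng.normal(size=(8, 8)),
                                 h=h, Dk=8 // h)
        X = rng.normal(size=(5, 8))
        for i in range(h):
            cols = slice(i * params.Dk, (i + 1) * params.Dk)
            _, w = scaled_dot_product_attention(X @ params.Wq[:, cols],
                                                X @ params.Wk[:, cols],
                                                X @ params.Wv[:, cols],
                                                Dk=params.Dk)
            np.testing.assert_allclose(w.sum(axis=1), 1.0)


def test_permutation_equivariance_without_positional_encoding():
    rng = np.random.default_rng(4)
    layer = MultiHeadAttention(8, 2, rng)
    X = rng.normal(size=(1, 6, 8))
    perm = rng.permutation(6)
    out = layer(Tensor(X)).data
    out_perm = layer(Tensor(X[:, perm])).data
    np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-12)


def test_indivisible_head_count_rejected():
    with pytest.raises(ValueError):
        MultiHeadAttention(10, 4, np.random.default_rng(0))
    with pytest.raises(ValueError):
        HeadConfig("FA", input_dim=100, n_classes=6, d_model=10, n_heads=4)


# -- heads --------------------------------------------------------------------

def test_fa_head_token_count_pads_824_to_13_tokens():
    cfg = HeadConfig("FA", input_dim=824, n_classes=6, d_model=64)
    assert cfg.token_count == 13
    model = build_head(cfg)
    assert isinstance(model, FANet)


@pytest.mark.parametrize("head_type", ["F", "FC", "FA"])
def test_head_forward_shape_and_seeded_initialization(head_type):
    cfg = HeadConfig(head_type, input_dim=50, n_classes=6, d_model=16,
                     hidden_dim=32, seed=5)
    m1, m2 = build_head(cfg), build_head(cfg)
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(p1.data, p2.data)
    X = np.random.default_rng(6).normal(size=(4, 50))
    assert m1(Tensor(X)).shape == (4, 6)


def test_unknown_head_type_rejected():
    with pytest.raises(ValueError):
        HeadConfig("Z", input_dim=10, n_classes=2)


@pytest.mark.parametrize("head_type", ["F", "FC", "FA"])
def test_one_adam_step_decreases_single_sample_loss(head_type):
    cfg = HeadConfig(head_type, input_dim=30, n_classes=4, d_model=16,
                     hidden_dim=16, seed=7)
    model = build_head(cfg)
    x = np.random.default_rng(8).normal(size=(1, 30))
    y = np.array([2])
    opt = Adam(model.parameters(), lr=1e-3)
    before = float(cross_entropy(model(Tensor(x)), y).data)
    loss = cross_entropy(model(Tensor(x)), y)
    loss.backward()
    opt.step()
    after = float(cross_entropy(model(Tensor(x)), y).data)
    assert after < before


@pytest.mark.parametrize("head_type", ["F", "FC", "FA"])
def test_heads_fit_separable_clusters_perfectly(head_type, separable_features):
    from leaffuse.evaluation import TrainConfig, train_head
    X, y, _ = separable_features
    idx = np.random.default_rng(9).permutation(len(y))[:60]
    cfg = HeadConfig(head_type, input_dim=16, n_classes=2, d_model=16,
                     hidden_dim=32, seed=10)
    model = build_head(cfg)
    model, _ = train_head(model, X[idx], y[idx],
                          config=TrainConfig(epochs=150, seed=11,
                                             lr_switch_epoch=75))
    acc = (predict_proba(model, X[idx]).argmax(axis=1) == y[idx]).mean()
    assert acc == 1.0


def test_predict_proba_rows_sum_to_one_and_shift_invariant():
    cfg = HeadConfig("F", input_dim=10, n_classes=3, hidden_dim=8, seed=12)
    model = build_head(cfg)
    X = np.random.default_rng(13).normal(size=(5, 10))
    proba = predict_proba(model, X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
    # shifting all logits by a constant leaves softmax unchanged
    model.fc2.bias.data += 7.5
    np.testing.assert_allclose(predict_proba(model, X), proba, atol=1e-9)
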