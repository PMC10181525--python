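"""Classification heads over feature vectors, including attention recoding.

Three head architectures classify a flat feature vector:

* **F-Net** — dense -> ReLU -> dense (plain fully connected classifier);
* **FC-Net** — the vector is treated as a 1-channel 1-D signal and recoded
  by two small convolutions with max-pooling before the dense classifier;
* **FA-Net** — the vector is zero-padded to a multiple of ``d_model``,
  reshaped into tokens, recoded by one multi-head attention layer
  (softmax(Q K^T / sqrt(Dk)) V per head, heads concatenated and projected),
  then classified by dense layers.

Applied to shallow features these are the S-/SC-/SA-Net variants; applied
to fused features the F-/FC-/FA-Net variants — the architecture is
identical, only the input differs.

:func:`scaled_dot_product_attention` and :func:`multi_head_attention` are
plain-numpy reference implementations (an explicit per-head loop); the
trainable :class:`MultiHeadAttention` layer computes the same function in
batched form on autodiff tensors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax
from .nn import Conv1d, Linear, Module

__all__ = [
    "AttentionParams", "HeadConfig",
    "scaled_dot_product_attention", "multi_head_attention",
    "MultiHeadAttention", "FNet", "FCNet", "FANet",
    "build_head", "predict_proba",
]


def scaled_dot_product_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                                 Dk: int | None = None
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """softmax(Q K^T / sqrt(Dk)) V; returns (output, attention weights)."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share the key dimension")
    if K.shape[0] != V.shape[0]:
        raise ValueError("K and V must have the same number of rows")
    Dk = Q.shape[-1] if Dk is None else Dk
    scores = Q @ K.T / math.sqrt(Dk)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights @ V, weights


@dataclass
class AttentionParams:
    """Explicit multi-head attention weights (full projection matrices;
    head ``i`` uses columns ``i*Dk:(i+1)*Dk``)."""

    Wq: np.ndarray  # (d_model, h * Dk)
    Wk: np.ndarray
    Wv: np.ndarray
    W0: np.ndarray  # (h * Dk, d_model)
    h: int
    Dk: int

    def __post_init__(self):
        if self.h < 1:
            raise ValueError("h must be >= 1")
        d = self.h * self.Dk
        for name in ("Wq", "Wk", "Wv"):
            if getattr(self, name).shape[1] != d:
                raise ValueError(f"{name} must have {d} columns")
        if self.W0.shape != (d, self.Wq.shape[0]):
            raise ValueError("W0 shape inconsistent with heads")


def multi_head_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Reference per-head loop: project, attend per head, concatenate, W0."""
    X = np.asarray(X, dtype=float)
    heads = []
    for i in range(params.h):
        cols = slice(i * params.Dk, (i + 1) * params.Dk)
        out, _ = scaled_dot_product_attention(
            X @ params.Wq[:, cols], X @ params.Wk[:, cols],
            X @ params.Wv[:, cols], Dk=params.Dk)
        heads.append(out)
    return np.concatenate(heads, axis=-1) @ params.W0


class MultiHeadAttention(Module):
    """Batched trainable multi-head attention over (B, n, d_model) tokens."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by h {n_heads}")
        self.d_model, self.h = d_model, n_heads
        self.dk = d_model // n_heads
        sd = 1.0 / math.sqrt(d_model)
        self.Wq = Tensor(rng.normal(0, sd, (d_model, d_model)), requires_grad=True)
        self.Wk = Tensor(rng.normal(0, sd, (d_model, d_model)), requires_grad=True)
        self.Wv = Tensor(rng.normal(0, sd, (d_model, d_model)), requires_grad=True)
        self.W0 = Tensor(rng.normal(0, sd, (d_model, d_model)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        B, n, d = x.shape

        def split(t: Tensor) -> Tensor:  # (B, n, d) -> (B, h, n, dk)
            return t.reshape(B, n, self.h, self.dk).transpose(0, 2, 1, 3)

        q = split(x @ self.Wq)
        k = split(x @ self.Wk)
        v = split(x @ self.Wv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk))
        att = softmax(scores, axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, n, d)
        return out @ self.W0

    def export_params(self) -> AttentionParams:
        return AttentionParams(self.Wq.data.copy(), self.Wk.data.copy(),
                               self.Wv.data.copy(), self.W0.data.copy(),
                               self.h, self.dk)


@dataclass(frozen=True)
class HeadConfig:
    head_type: str  # "F", "FC" or "FA"
    input_dim: int
    n_classes: int
    d_model: int = 64
    n_heads: int = 4
    hidden_dim: int = 512
    conv_channels: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.head_type not in ("F", "FC", "FA"):
            raise ValueError(f"unknown head_type {self.head_type!r}")
        if self.head_type == "FA" and self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.head_type == "FC" and self.conv_channels < 1:
            raise ValueError("conv_channels must be >= 1")

    @property
    def token_count(self) -> int:
        """Number of d_model-sized tokens after zero padding (FA head)."""
        return math.ceil(self.input_dim / self.d_model)


class FNet(Module):
    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.fc1 = Linear(config.input_dim, config.hidden_dim, rng)
        self.fc2 = Linear(config.hidden_dim, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class FCNet(Module):
    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        c = config.conv_channels
        self.conv1 = Conv1d(1, c, 3, rng, padding=1)
        self.conv2 = Conv1d(c, 2 * c, 3, rng, padding=1)
        self.fc = Linear(2 * c * (config.input_dim // 2), config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, D = x.shape
        y = self.conv1(x.reshape(B, 1, D)).relu().max_pool1d(2)
        y = self.conv2(y).relu()
        return self.fc(y.reshape(B, -1))


class FANet(Module):
    """Zero-pad to n x d_model tokens, recode with one attention layer,
    classify with dense layers.  No positional encoding: a flat feature
    vector carries no translation structure worth encoding."""

    def __init__(self, config: HeadConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.attn = MultiHeadAttention(config.d_model, config.n_heads, rng)
        n = config.token_count
        self.fc1 = Linear(n * config.d_model, config.hidden_dim, rng)
        self.fc2 = Linear(config.hidden_dim, config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, D = x.shape
        cfg = self.config
        pad = cfg.token_count * cfg.d_model - D
        tokens = x.pad_last(pad).reshape(B, cfg.token_count, cfg.d_model)
        y = self.attn(tokens).reshape(B, cfg.token_count * cfg.d_model)
        return self.fc2(self.fc1(y).relu())


_HEADS = {"F": FNet, "FC": FCNet, "FA": FANet}


def build_head(config: HeadConfig) -> Module:
    """Instantiate the configured head with seeded initialization."""
    return _HEADS[config.head_type](config)


def predict_proba(model: Module, features: np.ndarray) -> np.ndarray:
    """Softmax class probabilities, rows summing to 1."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    model.eval()
    logits = model(Tensor(X)).data
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
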