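"""Deep ("depth") feature extractors.

The reference architecture is a ConvNeXt-style convolutional network: four
stages of inverted-bottleneck blocks (depthwise 7x7 convolution -> layer
normalization -> pointwise expansion x4 -> GELU -> pointwise projection,
with a residual connection), 2x2/stride-2 downsampling between stages, and
a final layer normalization after global average pooling.  The *depth
feature* of an image is the output of that last normalization layer — the
pre-classifier embedding — whose length equals the last stage's channel
count (1024 for the Base configuration C=(128, 256, 512, 1024),
B=(3, 3, 27, 3)).

Pretrained weights are not bundled; builders initialize from a seed and
accept user-supplied weight files (``.npz`` from :meth:`Module.state_dict`).
A small three-convolution backbone (:func:`build_tiny_backbone`) provides
the same extraction contract at test-suite scale.  Any other extractor can
be plugged in as a plain callable ``images -> (n, feature_dim)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .autodiff import Tensor
from .nn import Conv2d, LayerNorm, Linear, Module

__all__ = [
    "BackboneSpec", "CONVNEXT_BASE", "ConvNeXt", "TinyBackbone",
    "build_convnext_base", "build_tiny_backbone", "preprocess_images",
    "extract_depth", "finetune_backbone",
]

#: per-channel standardization constants applied after scaling to [0, 1]
PREPROC_MEAN = 0.5
PREPROC_STD = 0.25


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    stage_channels: tuple[int, int, int, int]
    stage_blocks: tuple[int, int, int, int]
    kernel_size: int = 7
    expansion_ratio: int = 4
    input_size: int = 224

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.stage_blocks) != 4:
            raise ValueError("spec requires exactly four stages")
        if min(self.stage_channels) < 1 or min(self.stage_blocks) < 1:
            raise ValueError("stage channels and block counts must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    @property
    def feature_dim(self) -> int:
        return self.stage_channels[-1]

    @property
    def total_blocks(self) -> int:
        return sum(self.stage_blocks)


CONVNEXT_BASE = BackboneSpec("convnext-base", (128, 256, 512, 1024), (3, 3, 27, 3))


def _ln_nchw(ln: LayerNorm, x: Tensor) -> Tensor:
    """Apply a channels-last LayerNorm to an NCHW tensor."""
    return ln(x.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)


class _ConvNeXtBlock(Module):
    def __init__(self, dim: int, kernel: int, expansion: int,
                 rng: np.random.Generator):
        super().__init__()
        self.dw = Conv2d(dim, dim, kernel, rng, padding=kernel // 2, groups=dim)
        self.norm = LayerNorm(dim)
        self.pw1 = Linear(dim, expansion * dim, rng)
        self.pw2 = Linear(expansion * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.dw(x).transpose(0, 2, 3, 1)      # NHWC
        y = self.pw2(self.pw1(self.norm(y)).gelu())
        return x + y.transpose(0, 3, 1, 2)


class ConvNeXt(Module):
    """Four-stage ConvNeXt-style classifier with an embedding hook."""

    def __init__(self, spec: BackboneSpec, n_classes: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        C = spec.stage_channels
        self.spec = spec
        self.stem = Conv2d(3, C[0], 4, rng, stride=4)
        self.stem_norm = LayerNorm(C[0])
        self.stages: list[list[_ConvNeXtBlock]] = []
        self.downsamples: list[tuple[LayerNorm, Conv2d]] = []
        for s in range(4):
            if s > 0:
                self.downsamples.append(
                    (LayerNorm(C[s - 1]), Conv2d(C[s - 1], C[s], 2, rng, stride=2)))
            self.stages.append([
                _ConvNeXtBlock(C[s], spec.kernel_size, spec.expansion_ratio, rng)
                for _ in range(spec.stage_blocks[s])
            ])
        self.final_norm = LayerNorm(spec.feature_dim)
        self.classifier = Linear(spec.feature_dim, n_classes, rng)

    def parameters(self):
        params = super().parameters()
        for blocks in self.stages:
            for b in blocks:
                params.extend(b.parameters())
        for ln, conv in self.downsamples:
            params.extend(ln.parameters())
            params.extend(conv.parameters())
        return params

    def features(self, x: Tensor) -> Tensor:
        """Depth features: output of the last normalization layer
        (after global average pooling, before the classifier)."""
        y = _ln_nchw(self.stem_norm, self.stem(x))
        for s in range(4):
            if s > 0:
                ln, conv = self.downsamples[s - 1]
                y = conv(_ln_nchw(ln, y))
            for block in self.stages[s]:
                y = block(y)
        pooled = y.mean(axis=(2, 3))
        return self.final_norm(pooled)

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))

    @property
    def feature_dim(self) -> int:
        return self.spec.feature_dim


class TinyBackbone(Module):
    """Three strided convolutions + pooled LayerNorm embedding; fast enough
    to fine-tune inside a test suite while honoring the same contract."""

    def __init__(self, feature_dim: int = 32, n_classes: int = 6,
                 seed: int = 0, input_size: int = 64):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.conv1 = Conv2d(3, 16, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(16, 32, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(32, feature_dim, 3, rng, stride=2, padding=1)
        self.final_norm = LayerNorm(feature_dim)
        self.classifier = Linear(feature_dim, n_classes, rng)
        self._feature_dim = feature_dim

    def features(self, x: Tensor) -> Tensor:
        y = self.conv1(x).gelu()
        y = self.conv2(y).gelu()
        y = self.conv3(y).gelu()
        return self.final_norm(y.mean(axis=(2, 3)))

    def forward(self, x: Tensor) -> Tensor:
        return self.classifier(self.features(x))

    @property
    def feature_dim(self) -> int:
        return self._feature_dim


def build_convnext_base(spec: BackboneSpec = CONVNEXT_BASE, n_classes: int = 6,
                        seed: int = 0, weights: str | None = None) -> ConvNeXt:
    """Build a ConvNeXt; ``weights`` optionally points to an .npz state dict."""
    model = ConvNeXt(spec, n_classes, seed=seed)
    if weights is not None:
        with np.load(weights) as f:
            model.load_state_dict(dict(f))
    return model


def build_tiny_backbone(feature_dim: int = 32, n_classes: int = 6,
                        seed: int = 0, input_size: int = 64) -> TinyBackbone:
    return TinyBackbone(feature_dim, n_classes, seed=seed, input_size=input_size)


def preprocess_images(images, size: int) -> np.ndarray:
    """Resize to ``size`` x ``size``, scale to [0, 1], standardize; NCHW."""
    out = np.empty((len(images), 3, size, size))
    for k, img in enumerate(images):
        arr = np.asarray(img, dtype=float)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError("expected HxWx3 images")
        if arr.max() > 1.0:
            arr = arr / 255.0
        if arr.shape[:2] != (size, size):
            arr = resize(arr, (size, size), anti_aliasing=True,
                         preserve_range=True)
        out[k] = ((arr - PREPROC_MEAN) / PREPROC_STD).transpose(2, 0, 1)
    return out


def extract_depth(model, images, batch_size: int = 16,
                  preprocessed: bool = False) -> np.ndarray:
    """Depth features for a list/array of RGB images, shape (n, feature_dim).

    ``model`` is any object with ``.features`` and ``.feature_dim`` (or a
    plain callable ``images -> array`` plugin).  Deterministic in eval mode.
    """
    if callable(model) and not isinstance(model, Module):
        return np.asarray(model(images), dtype=float)
    size = getattr(model, "input_size", None) or getattr(model.spec, "input_size")
    x = np.asarray(images, dtype=float) if preprocessed \
        else preprocess_images(images, size)
    if x.ndim != 4 or x.shape[1] != 3:
        raise ValueError(f"expected (n, 3, H, W) input, got {x.shape}")
    model.eval()
    feats = []
    for start in range(0, len(x), batch_size):
        feats.append(model.features(Tensor(x[start:start + batch_size])).data)
    return np.concatenate(feats, axis=0)


def finetune_backbone(model: Module, images, labels, config=None,
                      split=None, preprocessed: bool = False):
    """Supervised fine-tuning of a backbone's classifier end to end.

    After training, :func:`extract_depth` on the returned model yields the
    learned depth features.  Returns ``(model, history)`` with per-epoch
    loss curves.
    """
    from .evaluation import TrainConfig, train_head  # deferred: avoids cycle

    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("empty dataset")
    if config is None:
        config = TrainConfig(epochs=10)
    size = getattr(model, "input_size", None) or getattr(model.spec, "input_size")
    x = np.asarray(images, dtype=float) if preprocessed \
        else preprocess_images(images, size)
    return train_head(model, x, labels, split=split, config=config)
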