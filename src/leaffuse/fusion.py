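"""Serial feature fusion with training-set standardization.

Fusion is concatenation, shallow block first: ``[shallow | depth]``
(792 + 1024 = 1816 values with the ConvNeXt-Base embedding).  Because
histogram entries (<= 1), raw GLCM statistics and network activations live
on incompatible scales, each feature is z-scored with a mean and standard
deviation estimated on the *training split only*; constant features pass
through centered (their SD is floored to 1).  Passing ``standardizer=None``
to :func:`fuse` keeps the literal unscaled concatenation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["Standardizer", "fit_standardizer", "fuse"]


@dataclass
class Standardizer:
    """Per-feature mean/SD (population convention, ddof=0)."""

    mean: np.ndarray
    sd: np.ndarray  # floored: SD < epsilon is replaced by 1
    epsilon: float
    n_fit: int

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.dim:
            raise ValueError(f"expected {self.dim} features, got {X.shape[-1]}")
        return (X - self.mean) / self.sd

    def to_json(self, path: str):
        with open(path, "w") as fh:
            json.dump({"mean": self.mean.tolist(), "sd": self.sd.tolist(),
                       "epsilon": self.epsilon, "n_fit": self.n_fit}, fh)

    @classmethod
    def from_json(cls, path: str) -> "Standardizer":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["mean"]), np.array(d["sd"]),
                   d["epsilon"], d["n_fit"])


def fit_standardizer(train_features: np.ndarray, split=None,
                     epsilon: float = 1e-12) -> Standardizer:
    """Fit on training samples only.

    If ``split`` labels are given, any sample flagged other than ``"train"``
    raises — the guard against val/test leakage.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D (samples x features) array")
    if split is not None:
        split = np.asarray(split)
        if split.shape[0] != X.shape[0]:
            raise ValueError("split length must match sample count")
        bad = set(split.tolist()) - {"train"}
        if bad:
            raise ValueError(
                f"standardizer must be fitted on the training split only; "
                f"got samples flagged {sorted(bad)}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    sd = np.where(sd < epsilon, 1.0, sd)
    return Standardizer(mean, sd, epsilon, X.shape[0])


def fuse(shallow: np.ndarray, depth: np.ndarray,
         standardizer: Standardizer | None = None) -> np.ndarray:
    """Standardized serial fusion ``[shallow | depth]``.

    Accepts single vectors or (n, d) batches; the standardizer must have
    been fitted on vectors of the combined dimensionality.
    """
    single = np.asarray(shallow).ndim == 1
    shallow = np.atleast_2d(np.asarray(shallow, dtype=float))
    depth = np.atleast_2d(np.asarray(depth, dtype=float))
    if shallow.shape[0] != depth.shape[0]:
        raise ValueError("shallow and depth batches differ in sample count")
    fused = np.concatenate([shallow, depth], axis=1)
    if standardizer is not None:
        fused = standardizer.transform(fused)
    return fused[0] if single else fused
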