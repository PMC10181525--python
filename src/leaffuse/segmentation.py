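"""Leaf/background separation by iterative threshold selection.

The threshold update is the classic Ridler–Calvard iteration: split the
gray histogram at T into regions R1 (below) and R2 (at/above), compute the
region means u1 and u2, and move T to their midpoint (u1 + u2) / 2 until it
stops changing.  Foreground polarity is resolved either explicitly or by
picking the side of the threshold with the larger mean color saturation
(leaves are saturated; dark or white studio backgrounds are not).  The raw
binary image is then cleaned to a single leaf mask: largest connected
component, holes filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .shallow import rgb_to_hsi

__all__ = ["ThresholdState", "iterative_threshold", "rgb_to_gray", "segment_leaf"]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ThresholdState:
    """Converged state of the iterative threshold: T and the region means."""
    T: float
    u1: float
    u2: float
    iterations: int
    converged: bool


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luminance grayscale on the 0–255 scale (weights 0.299/0.587/0.114)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if rgb.max() <= 1.0:
        rgb = rgb * 255.0
    return rgb @ _LUMA


def iterative_threshold(gray: np.ndarray, init: float | str = "global_mean",
                        tol: float = 0.5, max_iter: int = 100) -> ThresholdState:
    """Iterate T <- (u1 + u2) / 2 until |dT| < tol or max_iter.

    ``gray`` is any array of gray levels (conventionally 0–255); ``init``
    is a starting threshold or ``"global_mean"``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    g = np.asarray(gray, dtype=float).ravel()
    if np.unique(g).size < 2:
        raise ValueError("degenerate image: single gray level")
    T = float(np.mean(g)) if init == "global_mean" else float(init)
    u1 = u2 = T
    for it in range(1, max_iter + 1):
        below = g < T
        # guard: an empty side contributes the threshold itself
        u1 = float(g[below].mean()) if below.any() else T
        u2 = float(g[~below].mean()) if (~below).any() else T
        T_new = 0.5 * (u1 + u2)
        dT, T = abs(T_new - T), T_new
        if dT < tol:
            return ThresholdState(T, u1, u2, it, True)
    return ThresholdState(T, u1, u2, max_iter, False)


def segment_leaf(rgb: np.ndarray, polarity: str = "auto",
                 tol: float = 0.5, max_iter: int = 100) -> np.ndarray:
    """Return a boolean leaf mask for an RGB image.

    ``polarity`` is ``"bright_foreground"``, ``"dark_foreground"`` or
    ``"auto"`` (the side of the threshold with larger mean saturation wins).
    Keeps the largest connected component and fills its holes.
    """
    if polarity not in ("bright_foreground", "dark_foreground", "auto"):
        raise ValueError(f"unknown polarity {polarity!r}")
    gray = rgb_to_gray(rgb)
    state = iterative_threshold(gray, tol=tol, max_iter=max_iter)
    bright = gray >= state.T
    if polarity == "auto":
        rgb01 = np.asarray(rgb, dtype=float)
        if rgb01.max() > 1.0:
            rgb01 = rgb01 / 255.0
        _, S, _ = rgb_to_hsi(rgb01)
        s_bright = S[bright].mean() if bright.any() else -np.inf
        s_dark = S[~bright].mean() if (~bright).any() else -np.inf
        fg = bright if s_bright >= s_dark else ~bright
    elif polarity == "bright_foreground":
        fg = bright
    else:
        fg = ~bright
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    # bridge thin sub-threshold structures (dark veins) before picking the
    # largest component; closing is idempotent, so re-segmenting a returned
    # mask reproduces it
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)), iterations=2)
    lab, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        fg = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(fg)
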