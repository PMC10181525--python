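"""Handcrafted (shallow) image features: HSI color histograms and GLCM texture.

The shallow descriptor of a segmented leaf is the concatenation of

* a color histogram in the hue–saturation–intensity (HSI) space: 256 bins
  per channel over foreground pixels, channels ordered H, S, I -> 768 values;
* gray-level co-occurrence matrix (GLCM) statistics: six Haralick-style
  scalars at each of the four standard directions 0°, 45°, 90°, 135°
  (angle-major order) -> 24 values;

for 792 values in total.  Both parts are computed over the leaf mask only,
so background pixels never contribute.

HSI conversion uses the geometric (arccos) hue formula:

    I = (R + G + B) / 3
    S = 1 - 3 min(R, G, B) / (R + G + B)          (0 for black pixels)
    theta = arccos{ [(R-G) + (R-B)] / 2 / sqrt[(R-G)^2 + (R-B)(G-B)] }
    H = theta if B <= G else 2*pi - theta,  H := 0 wherever S = 0

with H in radians in [0, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "HsiImage", "Glcm", "ShallowConfig",
    "rgb_to_hsi", "color_histogram", "glcm", "texture_statistics",
    "texture_vector", "extract_shallow",
    "COLOR_DIM", "TEXTURE_DIM", "SHALLOW_DIM",
    "GLCM_ANGLES", "DEFAULT_STATS", "ALL_STATS",
]

COLOR_DIM = 768
TEXTURE_DIM = 24
SHALLOW_DIM = COLOR_DIM + TEXTURE_DIM  # 792

GLCM_ANGLES = (0, 45, 90, 135)
#: six statistics used by default; dissimilarity/energy are drop-in swaps
DEFAULT_STATS = ("ASM", "contrast", "correlation", "entropy", "IDM", "homogeneity")
ALL_STATS = ("ASM", "contrast", "correlation", "entropy", "IDM",
             "homogeneity", "dissimilarity", "energy")

# offsets in (row, col) for each direction, distance 1
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class HsiImage(NamedTuple):
    H: np.ndarray  # radians, [0, 2*pi)
    S: np.ndarray  # [0, 1]
    I: np.ndarray  # [0, 1]


def rgb_to_hsi(rgb: np.ndarray) -> HsiImage:
    """Convert an RGB image with channels in [0, 1] to HSI."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValueError("RGB channels must lie in [0, 1]")
    R, G, B = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = R + G + B
    I = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(R, G), B)
                     / np.where(total > 0, total, 1.0), 0.0)
        num = 0.5 * ((R - G) + (R - B))
        den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
        cosang = np.clip(np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0),
                         -1.0, 1.0)
    theta = np.arccos(cosang)
    H = np.where(B <= G, theta, 2.0 * np.pi - theta)
    H = np.where(S <= 1e-12, 0.0, H)
    return HsiImage(H, S, I)


def color_histogram(hsi: HsiImage, mask: np.ndarray,
                    bins_per_channel: int = 256,
                    normalization: str = "l1") -> np.ndarray:
    """Per-channel histogram over foreground pixels, concatenated H | S | I.

    In ``"l1"`` mode each 256-bin channel block sums to 1 (histograms are
    then invariant to image size); ``"count"`` keeps raw pair counts.
    """
    if normalization not in ("l1", "count"):
        raise ValueError(f"unknown normalization {normalization!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    ranges = [(0.0, 2.0 * np.pi), (0.0, 1.0), (0.0, 1.0)]
    blocks = []
    for chan, rng in zip(hsi, ranges):
        h, _ = np.histogram(chan[mask], bins=bins_per_channel, range=rng)
        h = h.astype(float)
        if normalization == "l1":
            h /= h.sum()
        blocks.append(h)
    return np.concatenate(blocks)


@dataclass(frozen=True)
class Glcm:
    """A (levels x levels) gray-level co-occurrence matrix and its settings."""
    p: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool
    normalized: bool


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization; range [0, 256) for 0-255 images, [0, 1] else."""
    g = np.asarray(gray, dtype=float)
    scale = 256.0 if g.max() > 1.0 else 1.0
    q = np.floor(g / scale * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(gray: np.ndarray, mask: np.ndarray | None = None, levels: int = 64,
         distance: int = 1, angle: int = 0, symmetric: bool = True,
         normalize: bool = True) -> Glcm:
    """Co-occurrence matrix counting only pairs with BOTH pixels in the mask.

    Offsets in (row, col): 0° -> (0, +d), 45° -> (-d, +d), 90° -> (-d, 0),
    135° -> (-d, -d).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}, got {angle}")
    gray = np.asarray(gray)
    if mask is None:
        mask = np.ones(gray.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    q = _quantize(gray, levels)
    dr, dc = (distance * o for o in _OFFSETS[angle])
    H, W = q.shape
    # source window such that (r + dr, c + dc) stays inside the image
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    src_i = q[r0:r1, c0:c1]
    src_m = mask[r0:r1, c0:c1]
    dst_i = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    dst_m = mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = src_m & dst_m
    if not valid.any():
        raise ValueError("no valid pixel pairs under the mask")
    p = np.zeros((levels, levels))
    np.add.at(p, (src_i[valid], dst_i[valid]), 1.0)
    if symmetric:
        p = p + p.T
    if normalize:
        p = p / p.sum()
    return Glcm(p, levels, distance, angle, symmetric, normalize)


def texture_statistics(g: Glcm, stat_set: tuple[str, ...] = DEFAULT_STATS
                       ) -> np.ndarray:
    """Evaluate the requested Haralick statistics on a normalized GLCM.

    ASM = sum p^2; energy = sqrt(ASM); contrast = sum (i-j)^2 p;
    dissimilarity = sum |i-j| p; correlation = sum (i-mu_i)(j-mu_j) p
    / (sigma_i sigma_j) (defined as 1 when a sigma vanishes);
    entropy = -sum p ln p (0 ln 0 := 0); IDM = sum p / (1 + (i-j)^2);
    homogeneity = sum p / (1 + |i-j|).
    """
    if not g.normalized:
        raise ValueError("texture statistics require a normalized GLCM")
    unknown = set(stat_set) - set(ALL_STATS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    p = g.p
    L = g.levels
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    sig_i = float(np.sqrt(((np.arange(L) - mu_i) ** 2 * pi).sum()))
    sig_j = float(np.sqrt(((np.arange(L) - mu_j) ** 2 * pj).sum()))
    asm = float((p ** 2).sum())
    values = {
        "ASM": asm,
        "energy": float(np.sqrt(asm)),
        "contrast": float((diff ** 2 * p).sum()),
        "dissimilarity": float((np.abs(diff) * p).sum()),
        "correlation": (float(((i - mu_i) * (j - mu_j) * p).sum() / (sig_i * sig_j))
                        if sig_i * sig_j > 0 else 1.0),
        "entropy": float(-(p[p > 0] * np.log(p[p > 0])).sum()),
        "IDM": float((p / (1.0 + diff ** 2)).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
    }
    return np.array([values[s] for s in stat_set])


@dataclass(frozen=True)
class ShallowConfig:
    bins_per_channel: int = 256
    normalization: str = "l1"
    levels: int = 64
    distance: int = 1
    symmetric: bool = True
    stat_set: tuple[str, ...] = DEFAULT_STATS


def texture_vector(gray: np.ndarray, mask: np.ndarray,
                   config: ShallowConfig = ShallowConfig()) -> np.ndarray:
    """24-dim texture vector: 6 statistics x 4 angles, angle-major order."""
    parts = []
    for angle in GLCM_ANGLES:
        g = glcm(gray, mask, levels=config.levels, distance=config.distance,
                 angle=angle, symmetric=config.symmetric, normalize=True)
        parts.append(texture_statistics(g, config.stat_set))
    return np.concatenate(parts)


def extract_shallow(rgb: np.ndarray, mask: np.ndarray,
                    config: ShallowConfig = ShallowConfig()) -> np.ndarray:
    """Full shallow descriptor: color histogram (768) | texture (24) = 792."""
    from .segmentation import rgb_to_gray  # local import avoids a cycle

    rgb = np.asarray(rgb, dtype=float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    hsi = rgb_to_hsi(rgb)
    color = color_histogram(hsi, mask, config.bins_per_channel,
                            config.normalization)
    gray = rgb_to_gray(rgb)
    texture = texture_vector(gray, mask, config)
    return np.concatenate([color, texture])
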