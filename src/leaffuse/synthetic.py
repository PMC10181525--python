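"""Synthetic leaf images and feature-space clusters for pipeline testing.

Real nutrient-deficiency leaf collections are rarely public, so this module
provides two seeded generators:

* :func:`generate_leaf_image` draws a single elliptical leaf with a vein
  skeleton on a dark textured background.  Six default recipes emulate the
  visual phenotypes of the common deficiencies: nitrogen-starved leaves
  yellow uniformly, magnesium deficiency shows interveinal yellow spots,
  iron deficiency a pale yellow-white reticulate mesh, phosphorus deficiency
  dark green tissue with reddish veins, and potassium deficiency yellowed,
  crinkled margins.  The recipes only need to be *distinguishable* by color
  and texture features, not botanically exact.

* :func:`generate_feature_clusters` skips the image stage entirely and
  samples Gaussian class clusters directly in a (shallow | depth) feature
  space.  Designating a *confusable pair* makes the two classes' depth-block
  means coincide while their shallow-block means stay separated — the
  feature-space analogue of two deficiencies that look alike to a deep
  network but differ in a handcrafted color feature.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.ndimage import gaussian_filter

__all__ = [
    "CLASS_NAMES",
    "LeafRecipe",
    "LeafSample",
    "ClusterSpec",
    "default_recipes",
    "generate_leaf_image",
    "generate_dataset",
    "stratified_split",
    "default_cluster_spec",
    "generate_feature_clusters",
]

#: Class order used throughout the package.
CLASS_NAMES = ("Healthy", "Fe", "K", "Mg", "N", "P")

SPOT_PATTERNS = ("none", "interveinal_spots", "edge_yellowing",
                 "reticulate_veins", "red_veins")


@dataclass(frozen=True)
class LeafRecipe:
    """Color/texture recipe for one deficiency class.

    ``base_hue`` is in degrees on the usual color wheel (60 = yellow,
    120 = green); ``texture_roughness`` scales fine-grained intensity noise
    (dimensionless, >= 0); ``leaf_axes`` fixes the ellipse semi-axes in
    pixels, or ``None`` to scale them with the image size.
    """

    class_label: str
    base_hue: float
    hue_jitter: float = 6.0
    spot_pattern: str = "none"
    texture_roughness: float = 0.03
    leaf_axes: tuple[int, int] | None = None
    saturation: float = 0.75
    intensity: float = 0.55

    def __post_init__(self):
        if not 0.0 <= self.base_hue < 360.0:
            raise ValueError(f"base_hue must be in [0, 360), got {self.base_hue}")
        if self.texture_roughness < 0:
            raise ValueError("texture_roughness must be >= 0")
        if self.spot_pattern not in SPOT_PATTERNS:
            raise ValueError(f"unknown spot_pattern {self.spot_pattern!r}")


def default_recipes() -> dict[str, LeafRecipe]:
    """One recipe per class; Fe and N are deliberately close in hue."""
    return {
        "Healthy": LeafRecipe("Healthy", base_hue=120.0),
        "Fe": LeafRecipe("Fe", base_hue=58.0, spot_pattern="reticulate_veins",
                         saturation=0.55, intensity=0.68, texture_roughness=0.04),
        "K": LeafRecipe("K", base_hue=105.0, spot_pattern="edge_yellowing",
                        texture_roughness=0.10),
        "Mg": LeafRecipe("Mg", base_hue=90.0, spot_pattern="interveinal_spots",
                         hue_jitter=8.0, texture_roughness=0.04),
        "N": LeafRecipe("N", base_hue=75.0, hue_jitter=8.0),
        "P": LeafRecipe("P", base_hue=140.0, spot_pattern="red_veins",
                        intensity=0.55, texture_roughness=0.05),
    }


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    n = gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
    sd = n.std()
    return n / sd if sd > 0 else n


def generate_leaf_image(recipe: LeafRecipe, size: int = 256, seed: int = 0,
                        background_mean: float = 30.0 / 255.0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render one leaf; returns (rgb uint8 HxWx3, ground-truth bool mask)."""
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    if recipe.leaf_axes is not None:
        a, b = recipe.leaf_axes
    else:
        a, b = 0.38 * size, 0.26 * size
    if 2 * max(a, b) + 4 > size:
        raise ValueError(
            f"leaf_axes {(a, b)} do not fit inside a {size}x{size} image")

    rng = np.random.default_rng(seed)
    angle = rng.uniform(-0.35, 0.35)
    cy, cx = size / 2.0, size / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    # leaf-local coordinates: u along the major axis, v along the minor
    u = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    v = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = r2 <= 1.0

    # vein skeleton: midrib plus paired oblique side veins
    vein = np.abs(v) < max(1.0, size / 180.0)
    spacing = a / 4.0
    slope = 0.7
    for k in range(-3, 4):
        u_k = k * spacing
        branch = (np.abs(np.abs(v) - slope * (u - u_k)) < max(1.0, size / 220.0))
        vein |= branch & (u >= u_k)
    vein &= mask

    hue = recipe.base_hue + recipe.hue_jitter * _smooth_noise(rng, size, size / 16.0)
    sat = np.full((size, size), recipe.saturation) \
        + 0.05 * _smooth_noise(rng, size, size / 16.0)
    inten = np.full((size, size), recipe.intensity) \
        + recipe.texture_roughness * _smooth_noise(rng, size, 1.5) \
        + 0.05 * _smooth_noise(rng, size, size / 12.0)

    pat = recipe.spot_pattern
    if pat == "interveinal_spots":
        spots = (_smooth_noise(rng, size, size / 24.0) > 0.9) & ~vein
        hue = np.where(spots, 58.0, hue)
        inten = np.where(spots, inten + 0.12, inten)
    elif pat == "edge_yellowing":
        edge = r2 > 0.62
        hue = np.where(edge, 0.35 * hue + 0.65 * 58.0, hue)
        inten = np.where(edge, inten + 0.06, inten)
    elif pat == "reticulate_veins":
        mesh = (np.abs(np.sin(u * 0.35)) < 0.18) | (np.abs(np.sin(v * 0.35)) < 0.18)
        sat = np.where(mesh, sat - 0.25, sat)
        inten = np.where(mesh, inten + 0.12, inten)
    if pat == "red_veins":
        hue = np.where(vein, 0.0, hue)
        sat = np.where(vein, 0.85, sat)
        inten = np.where(vein, inten + 0.12, inten)
    else:
        sat = np.where(vein, sat - 0.2, sat)
        inten = np.where(vein, inten + 0.1, inten)

    hsv = np.stack([np.mod(hue, 360.0) / 360.0,
                    np.clip(sat, 0.0, 1.0),
                    np.clip(inten, 0.05, 1.0)], axis=-1)
    leaf_rgb = hsv_to_rgb(hsv)

    bg = background_mean + 0.04 * rng.standard_normal((size, size))
    bg_rgb = np.clip(bg, 0.0, 1.0)[..., None].repeat(3, axis=-1)

    rgb = np.where(mask[..., None], leaf_rgb, bg_rgb)
    return (np.clip(rgb, 0.0, 1.0) * 255.0).round().astype(np.uint8), mask


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    order = np.argsort([c - e for c, e in zip(counts, exact)])  # largest remainder first
    for i in range(short):
        counts[order[i]] += 1
    return counts


def stratified_split(labels, seed: int,
                     ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
                     ) -> np.ndarray:
    """Assign each sample to train/val/test, 7:2:1 within every class.

    Counts use largest-remainder rounding so the three parts always sum to
    the class total; the assignment is a pure function of ``seed``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = np.empty(len(labels), dtype=object)
    for lab in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lab)
        perm = rng.permutation(len(idx))
        n_tr, n_va, n_te = _largest_remainder(len(idx), ratios)
        names = ["train"] * n_tr + ["val"] * n_va + ["test"] * n_te
        for p, name in zip(perm, names):
            out[idx[p]] = name
    return out.astype(str)


@dataclass
class LeafSample:
    image: np.ndarray
    mask: np.ndarray
    label: str
    split: str
    sample_id: str


def generate_dataset(recipes: dict[str, LeafRecipe] | None = None,
                     n_per_class: int = 10, size: int = 256, seed: int = 0,
                     background_mean: float = 30.0 / 255.0) -> list[LeafSample]:
    """Generate a labeled, split image set (7:2:1 train/val/test per class)."""
    if n_per_class < 10:
        raise ValueError(f"n_per_class must be >= 10, got {n_per_class}")
    recipes = recipes if recipes is not None else default_recipes()
    ss = np.random.SeedSequence(seed)
    image_seeds = ss.generate_state(len(recipes) * n_per_class) % (2 ** 31)
    samples: list[LeafSample] = []
    labels = []
    i = 0
    for label in sorted(recipes):
        recipe = recipes[label]
        for j in range(n_per_class):
            img, mask = generate_leaf_image(recipe, size=size,
                                            seed=int(image_seeds[i]),
                                            background_mean=background_mean)
            samples.append(LeafSample(img, mask, label, "", f"{label}_{j:04d}"))
            labels.append(label)
            i += 1
    split = stratified_split(labels, seed=seed + 1)
    for s, sp in zip(samples, split):
        s.split = sp
    return samples


# -- feature-space clusters ---------------------------------------------------

@dataclass
class ClusterSpec:
    """Gaussian class clusters in a (shallow | depth) feature space."""

    n_classes: int
    shallow_dim: int
    depth_dim: int
    shallow_means: np.ndarray  # (n_classes, shallow_dim)
    depth_means: np.ndarray    # (n_classes, depth_dim)
    covariance_scale: float = 1.0
    confusable_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_classes < 2 or self.shallow_dim < 1 or self.depth_dim < 1:
            raise ValueError("dimensions must be positive, n_classes >= 2")
        self.shallow_means = np.asarray(self.shallow_means, dtype=float)
        self.depth_means = np.asarray(self.depth_means, dtype=float)
        if self.shallow_means.shape != (self.n_classes, self.shallow_dim):
            raise ValueError("shallow_means shape mismatch")
        if self.depth_means.shape != (self.n_classes, self.depth_dim):
            raise ValueError("depth_means shape mismatch")
        for i, j in self.confusable_pairs:
            if not (0 <= i < self.n_classes and 0 <= j < self.n_classes):
                raise ValueError(f"confusable pair ({i}, {j}) out of range")


def default_cluster_spec(n_classes: int = 6, shallow_dim: int = 16,
                         depth_dim: int = 16, separation: float = 3.0,
                         covariance_scale: float = 1.0,
                         confusable_pairs: list[tuple[int, int]] | None = None,
                         ) -> ClusterSpec:
    """Axis-aligned class means; the default confusable pair is (Fe, N).

    Class ``i``'s mean is ``separation`` along coordinate ``i`` in both
    blocks, except that for each confusable pair the *depth* means are made
    identical — only the shallow block can tell those two classes apart.
    """
    if shallow_dim < n_classes or depth_dim < n_classes:
        raise ValueError("block dims must be >= n_classes for one-hot means")
    if confusable_pairs is None:
        confusable_pairs = [(CLASS_NAMES.index("Fe"), CLASS_NAMES.index("N"))] \
            if n_classes == len(CLASS_NAMES) else []
    shallow_means = separation * np.eye(n_classes, shallow_dim)
    depth_means = separation * np.eye(n_classes, depth_dim)
    for i, j in confusable_pairs:
        depth_means[j] = depth_means[i]
    return ClusterSpec(n_classes, shallow_dim, depth_dim, shallow_means,
                       depth_means, covariance_scale, list(confusable_pairs))


def generate_feature_clusters(spec: ClusterSpec, n_per_class: int, seed: int
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample labeled feature vectors.

    Returns ``(shallow_block, depth_block, labels)`` with shapes
    ``(n, shallow_dim)``, ``(n, depth_dim)`` and integer labels ``(n,)``.
    """
    if spec.covariance_scale <= 0:
        raise ValueError("covariance_scale must be > 0")
    rng = np.random.default_rng(seed)
    shallow, depth, labels = [], [], []
    for c in range(spec.n_classes):
        shallow.append(spec.shallow_means[c]
                       + spec.covariance_scale
                       * rng.standard_normal((n_per_class, spec.shallow_dim)))
        depth.append(spec.depth_means[c]
                     + spec.covariance_scale
                     * rng.standard_normal((n_per_class, spec.depth_dim)))
        labels.append(np.full(n_per_class, c))
    return (np.concatenate(shallow), np.concatenate(depth),
            np.concatenate(labels).astype(int))
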