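"""HSI conversion, color histograms, GLCM and Haralick statistics."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from leaffuse.segmentation import rgb_to_gray
from leaffuse.shallow import (ALL_STATS, COLOR_DIM, DEFAULT_STATS, GLCM_ANGLES,
                              SHALLOW_DIM, TEXTURE_DIM, Glcm, ShallowConfig,
                              color_histogram, extract_shallow, glcm,
                              rgb_to_hsi, texture_statistics, texture_vector)


def _naive_glcm(q, mask, levels, d, angle, symmetric=True):
    """Brute-force pair enumeration oracle."""
    offs = {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[angle]
    H, W = q.shape
    p = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + offs[0], c + offs[1]
            if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                p[q[r, c], q[r2, c2]] += 1
    if symmetric:
        p = p + p.T
    return p / p.sum()


# -- HSI ----------------------------------------------------------------------

@pytest.mark.parametrize("rgb,expected", [
    ((0.5, 0.5, 0.5), (0.0, 0.0, 0.5)),            # gray: S=0 forces H=0
    ((1.0, 0.0, 0.0), (0.0, 1.0, 1.0 / 3.0)),      # pure red
    ((0.0, 0.0, 1.0), (4 * np.pi / 3, 1.0, 1.0 / 3.0)),  # pure blue
    ((0.0, 1.0, 0.0), (2 * np.pi / 3, 1.0, 1.0 / 3.0)),  # pure green
    ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),            # black: conventions
])
def test_hsi_closed_forms(rgb, expected):
    H, S, I = rgb_to_hsi(np.array(rgb).reshape(1, 1, 3))
    assert (H[0, 0], S[0, 0], I[0, 0]) == pytest.approx(expected, abs=1e-12)


def test_hsi_ranges_on_random_images():
    rng = np.random.default_rng(0)
    H, S, I = rgb_to_hsi(rng.uniform(size=(32, 32, 3)))
    assert (H >= 0).all() and (H < 2 * np.pi).all()
    assert (S >= 0).all() and (S <= 1).all()
    assert (I >= 0).all() and (I <= 1).all()


def test_hsi_rejects_out_of_range_channels():
    with pytest.raises(ValueError):
        rgb_to_hsi(np.full((2, 2, 3), 2.0))


# -- color histogram ----------------------------------------------------------

def test_histogram_length_and_l1_normalization():
    rng = np.random.default_rng(1)
    hsi = rgb_to_hsi(rng.uniform(size=(16, 16, 3)))
    h = color_histogram(hsi, np.ones((16, 16), dtype=bool))
    assert h.shape == (COLOR_DIM,)
    for block in h.reshape(3, 256):
        assert block.sum() == pytest.approx(1.0)


def test_constant_color_foreground_hits_single_bin_per_channel():
    img = np.zeros((8, 8, 3))
    img[..., 0] = 0.8
    img[..., 1] = 0.3
    img[..., 2] = 0.1
    h = color_histogram(rgb_to_hsi(img), np.ones((8, 8), dtype=bool))
    for block in h.reshape(3, 256):
        assert (block > 0).sum() == 1
        assert block.max() == pytest.approx(1.0)


def test_histogram_invariant_to_pixel_replication():
    rng = np.random.default_rng(2)
    img = rng.uniform(size=(8, 8, 3))
    big = np.repeat(np.repeat(img, 2, axis=0), 2, axis=1)
    h1 = color_histogram(rgb_to_hsi(img), np.ones((8, 8), dtype=bool))
    h2 = color_histogram(rgb_to_hsi(big), np.ones((16, 16), dtype=bool))
    np.testing.assert_allclose(h1, h2)


def test_empty_mask_raises():
    hsi = rgb_to_hsi(np.zeros((4, 4, 3)))
    with pytest.raises(ValueError, match="empty mask"):
        color_histogram(hsi, np.zeros((4, 4), dtype=bool))


# -- GLCM ---------------------------------------------------------------------

def test_glcm_two_by_two_horizontal_and_vertical():
    img = np.array([[0.0, 0.0], [1.0, 1.0]])
    np.testing.assert_allclose(glcm(img, levels=2, angle=0).p,
                               [[0.5, 0.0], [0.0, 0.5]])
    np.testing.assert_allclose(glcm(img, levels=2, angle=90).p,
                               [[0.0, 0.5], [0.5, 0.0]])


def test_glcm_constant_image_single_diagonal_entry():
    g = glcm(np.full((6, 6), 80.0), levels=64, angle=0)
    assert g.p.sum() == pytest.approx(1.0)
    nz = np.nonzero(g.p)
    assert len(nz[0]) == 1 and nz[0][0] == nz[1][0]


@pytest.mark.parametrize("angle", GLCM_ANGLES)
def test_glcm_matches_naive_enumeration_with_random_masks(angle):
    rng = np.random.default_rng(angle)
    for _ in range(25):
        img = rng.integers(0, 256, size=(16, 16)).astype(float)
        mask = rng.uniform(size=(16, 16)) > 0.3
        q = np.clip(np.floor(img / 256 * 8), 0, 7).astype(int)
        expected = _naive_glcm(q, mask, 8, 1, angle)
        np.testing.assert_array_equal(glcm(img, mask, levels=8, angle=angle).p,
                                      expected)


@pytest.mark.parametrize("angle,skimage_angle", [(0, 0.0), (90, np.pi / 2)])
def test_glcm_cross_checks_against_skimage(angle, skimage_angle):
    """Independent library oracle on a full mask (axis-aligned directions)."""
    rng = np.random.default_rng(3)
    img = rng.integers(0, 8, size=(12, 12))
    ours = glcm(img.astype(float) / 8.0, levels=8, angle=angle).p
    ref = graycomatrix(img.astype(np.uint8), [1], [skimage_angle], levels=8,
                       symmetric=True, normed=True)[:, :, 0, 0]
    np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_glcm_rotation_maps_0_to_90_degrees():
    rng = np.random.default_rng(4)
    img = rng.integers(0, 256, size=(10, 10)).astype(float)
    g0 = glcm(img, levels=16, angle=0).p
    g90 = glcm(np.rot90(img), levels=16, angle=90).p
    np.testing.assert_array_equal(g0, g90)


def test_glcm_mirror_symmetry_at_0_degrees():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 256, size=(9, 11)).astype(float)
    np.testing.assert_array_equal(glcm(img, angle=0).p,
                                  glcm(img[:, ::-1], angle=0).p)


def test_glcm_rejects_bad_arguments():
    img = np.array([[0.0, 1.0]])
    with pytest.raises(ValueError):
        glcm(img, levels=1)
    with pytest.raises(ValueError):
        glcm(img, angle=30)
    with pytest.raises(ValueError, match="no valid pixel pairs"):
        glcm(img, mask=np.array([[True, False]]), angle=0)


# -- Haralick statistics ------------------------------------------------------

def test_constant_image_statistic_limits():
    g = glcm(np.full((8, 8), 0.5), levels=4, angle=0)
    stats = dict(zip(ALL_STATS, texture_statistics(g, ALL_STATS)))
    assert stats["ASM"] == 1.0
    assert stats["contrast"] == 0.0
    assert stats["entropy"] == 0.0
    assert stats["IDM"] == 1.0
    assert stats["dissimilarity"] == 0.0
    assert stats["energy"] == 1.0


def test_statistics_on_diagonal_and_antidiagonal_matrices():
    diag = Glcm(np.array([[0.5, 0.0], [0.0, 0.5]]), 2, 1, 0, True, True)
    s = dict(zip(DEFAULT_STATS, texture_statistics(diag)))
    assert s["contrast"] == 0.0
    assert s["ASM"] == 0.5
    assert s["entropy"] == pytest.approx(np.log(2))
    assert s["correlation"] == 1.0
    anti = Glcm(np.array([[0.0, 0.5], [0.5, 0.0]]), 2, 1, 0, True, True)
    s = dict(zip(DEFAULT_STATS, texture_statistics(anti)))
    assert s["contrast"] == 1.0
    assert s["correlation"] == -1.0
    assert s["IDM"] == 0.5


def test_unnormalized_matrix_is_rejected():
    g = glcm(np.array([[0.0, 1.0], [0.0, 1.0]]), levels=2, angle=0,
             normalize=False)
    with pytest.raises(ValueError, match="normalized"):
        texture_statistics(g)


# -- full shallow vector ------------------------------------------------------

def test_shallow_vector_dimensions(healthy_leaf):
    img, mask = healthy_leaf
    vec = extract_shallow(img, mask)
    assert vec.shape == (SHALLOW_DIM,)
    assert SHALLOW_DIM == COLOR_DIM + TEXTURE_DIM == 792
    tex = texture_vector(rgb_to_gray(img), mask)
    assert tex.shape == (TEXTURE_DIM,)
    np.testing.assert_array_equal(vec[COLOR_DIM:], tex)


def test_background_pixels_do_not_affect_shallow_features(healthy_leaf):
    img, mask = healthy_leaf
    scrambled = img.copy()
    scrambled[~mask] = 255 - scrambled[~mask]
    np.testing.assert_array_equal(extract_shallow(img, mask),
                                  extract_shallow(scrambled, mask))


def test_shallow_extraction_is_deterministic(healthy_leaf):
    img, mask = healthy_leaf
    np.testing.assert_array_equal(extract_shallow(img, mask),
                                  extract_shallow(img, mask))


def test_alternative_stat_set_keeps_dimension(healthy_leaf):
    img, mask = healthy_leaf
    cfg = ShallowConfig(stat_set=("dissimilarity", "energy", "contrast",
                                  "correlation", "entropy", "homogeneity"))
    assert extract_shallow(img, mask, cfg).shape == (SHALLOW_DIM,)
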