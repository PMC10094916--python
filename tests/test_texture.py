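"""Gray conversion and GLCM texture statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import brute_contrast, brute_glcm_counts, brute_homogeneity
from hyperskin.envi import HyperCube, ROI, default_wavelength_grid
from hyperskin.texture import (
    CooccurrenceMatrix,
    GLCMParams,
    GrayImage,
    brightness,
    cube_to_gray,
    glcm,
    glcm_contrast,
    glcm_homogeneity,
    texture_metrics,
)


def refl_cube(pixel_values_cu, bands=6):
    """Cube whose pixels have flat spectra at the given c.u. values."""
    arr = np.asarray(pixel_values_cu, dtype=float)
    data = np.repeat(arr[:, :, None], bands, axis=2)
    return HyperCube(data, default_wavelength_grid(bands), calibrated=True)


def full_roi(cube):
    return ROI(0, 0, cube.shape[0], cube.shape[1])


# --------------------------------------------------------------------------
# cube_to_gray


def test_full_scale_reflectance_maps_to_top_level():
    cube = refl_cube([[1023.0, 1023.0]])
    img = cube_to_gray(cube, full_roi(cube), levels=256)
    assert img.pixels.tolist() == [[255, 255]]


def test_zero_reflectance_maps_to_zero():
    cube = refl_cube([[0.0, 0.0]])
    assert cube_to_gray(cube, full_roi(cube)).pixels.tolist() == [[0, 0]]


def test_midpoint_rounds_half_up():
    # band-mean 511.5 on the 1023 scale -> 255 * 0.5 = 127.5 -> 128
    cube = refl_cube([[511.5, 511.5]])
    assert cube_to_gray(cube, full_roi(cube)).pixels.tolist() == [[128, 128]]


def test_uncalibrated_cube_rejected():
    cube = HyperCube(np.zeros((1, 2, 3)), default_wavelength_grid(3), calibrated=False)
    with pytest.raises(ValueError, match="calibrated"):
        cube_to_gray(cube, ROI(0, 0, 1, 2))


# --------------------------------------------------------------------------
# GLCM construction


def test_two_pair_example():
    img = GrayImage(np.array([[0, 0], [1, 1]]), levels=2)
    m = glcm(img, GLCMParams(levels=2))
    np.testing.assert_allclose(m.p, [[0.5, 0.0], [0.0, 0.5]])


def test_constant_image_single_diagonal_entry():
    img = GrayImage(np.full((5, 7), 3), levels=8)
    m = glcm(img, GLCMParams(levels=8))
    assert m.p[3, 3] == 1.0
    assert m.p.sum() == 1.0


def test_image_too_small_for_offset_errors():
    img = GrayImage(np.array([[1], [2]]), levels=4)  # 2x1: no horizontal pair
    with pytest.raises(ValueError, match="no pixel pair"):
        glcm(img, GLCMParams(levels=4))


@pytest.mark.parametrize("theta,expect", [
    (0, (1, 0)), (45, (1, -1)), (90, (0, -1)), (135, (-1, -1)),
])
def test_offset_convention(theta, expect):
    assert GLCMParams(theta_deg=theta).offset == expect


def test_exhaustive_tiny_images_match_oracle():
    """Every 2x2 binary and every 1x3 ternary image matches the oracle."""
    for vals in itertools.product(range(2), repeat=4):
        px = np.array(vals).reshape(2, 2)
        m = glcm(GrayImage(px, levels=2), GLCMParams(levels=2))
        counts = brute_glcm_counts(px, 2, 1, 0)
        np.testing.assert_allclose(m.p, counts / counts.sum())
    for vals in itertools.product(range(3), repeat=3):
        px = np.array(vals).reshape(1, 3)
        m = glcm(GrayImage(px, levels=3), GLCMParams(levels=3))
        counts = brute_glcm_counts(px, 3, 1, 0)
        np.testing.assert_allclose(m.p, counts / counts.sum())


@pytest.mark.parametrize("theta", [0, 45, 90, 135])
@pytest.mark.parametrize("symmetric", [False, True])
def test_small_random_images_match_oracle_all_angles(theta, symmetric):
    rng = np.random.default_rng(42)
    params = GLCMParams(theta_deg=theta, levels=8, symmetric=symmetric)
    dx, dy = params.offset
    for rows in range(1, 9):
        for cols in range(1, 9):
            px = rng.integers(0, 8, size=(rows, cols))
            counts = brute_glcm_counts(px, 8, dx, dy, symmetric)
            if counts.sum() == 0:
                continue
            m = glcm(GrayImage(px, levels=8), params)
            np.testing.assert_allclose(m.p, counts / counts.sum())
            assert abs(glcm_contrast(m) - brute_contrast(m.p)) < 1e-12
            assert abs(glcm_homogeneity(m) - brute_homogeneity(m.p)) < 1e-12


def test_matches_skimage_graycomatrix():
    """Cross-check matrix and contrast against scikit-image on θ=0, d=1."""
    skimage_feature = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(11)
    for _ in range(5):
        px = rng.integers(0, 16, size=(12, 14)).astype(np.uint8)
        ours = glcm(GrayImage(px, levels=16), GLCMParams(levels=16))
        ref = skimage_feature.graycomatrix(
            px, distances=[1], angles=[0], levels=16, symmetric=False, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours.p, ref)
        ref_contrast = skimage_feature.graycoprops(
            skimage_feature.graycomatrix(px, [1], [0], levels=16, normed=True),
            "contrast",
        )[0, 0]
        assert abs(glcm_contrast(ours) - ref_contrast) < 1e-9


def test_symmetric_mode_is_transpose_invariant():
    rng = np.random.default_rng(5)
    px = rng.integers(0, 6, size=(6, 6))
    m = glcm(GrayImage(px, levels=6), GLCMParams(levels=6, symmetric=True))
    np.testing.assert_allclose(m.p, m.p.T)


# --------------------------------------------------------------------------
# Texture statistics


def matrix_from_pairs(pairs, levels):
    """Normalised matrix putting equal mass on the given (i, j) pairs."""
    p = np.zeros((levels, levels))
    for i, j in pairs:
        p[i, j] += 1
    return CooccurrenceMatrix(p / p.sum(), GLCMParams(levels=levels))


def test_contrast_zero_for_diagonal_mass():
    m = matrix_from_pairs([(2, 2), (5, 5)], 8)
    assert glcm_contrast(m) == 0.0
    assert glcm_homogeneity(m) == 1.0


def test_contrast_one_for_unit_steps():
    m = matrix_from_pairs([(1, 2), (4, 3)], 8)
    assert glcm_contrast(m) == pytest.approx(1.0)
    assert glcm_homogeneity(m) == pytest.approx(0.5)


def test_single_extreme_pair_contrast():
    img = GrayImage(np.array([[0, 255]]), levels=256)
    m = glcm(img, GLCMParams())
    assert glcm_contrast(m) == pytest.approx(255**2)


def test_three_level_mixture_homogeneity():
    # P(|i-j|=0)=0.18, P(|i-j|=1)=0.74, P(|i-j|=8)=0.08
    p = np.zeros((16, 16))
    p[3, 3] = 0.18
    p[4, 5] = 0.74
    p[2, 10] = 0.08
    m = CooccurrenceMatrix(p, GLCMParams(levels=16))
    expected = 0.18 + 0.74 / 2 + 0.08 / 9
    assert glcm_homogeneity(m) == pytest.approx(expected)
    assert expected == pytest.approx(0.5589, abs=5e-4)


def test_brightness_examples():
    assert brightness(GrayImage(np.full((3, 3), 143), levels=256)) == 143.0
    assert brightness(GrayImage(np.array([[0, 255]]), levels=256)) == 127.5


@given(arrays(np.int64, (4, 5), elements=st.integers(0, 7)))
def test_brightness_equals_sum_over_count(px):
    img = GrayImage(px, levels=8)
    total = sum(int(v) for row in px for v in row)
    assert brightness(img) == pytest.approx(total / px.size)


@given(arrays(np.int64, (4, 6), elements=st.integers(0, 5)), st.integers(1, 2))
def test_shift_covariance(px, k):
    """Adding k to all levels moves brightness by k, leaves GLCM stats."""
    img = GrayImage(px, levels=8)
    shifted = GrayImage(px + k, levels=8)
    p = GLCMParams(levels=8)
    assert brightness(shifted) == pytest.approx(brightness(img) + k)
    assert glcm_contrast(glcm(shifted, p)) == pytest.approx(glcm_contrast(glcm(img, p)))
    assert glcm_homogeneity(glcm(shifted, p)) == pytest.approx(
        glcm_homogeneity(glcm(img, p)))


@given(arrays(np.int64, (5, 5), elements=st.integers(0, 7)))
def test_contrast_homogeneity_bounds_and_boundary_theorem(px):
    img = GrayImage(px, levels=8)
    m = glcm(img, GLCMParams(levels=8))
    c, h = glcm_contrast(m), glcm_homogeneity(m)
    assert 0.0 <= c <= 49.0
    assert 0.0 < h <= 1.0
    assert abs(m.p.sum() - 1.0) < 1e-9
    # contrast is zero exactly when homogeneity is one
    assert (c == pytest.approx(0.0, abs=1e-12)) == (h == pytest.approx(1.0))


def test_vertical_flip_preserves_glcm_stats():
    rng = np.random.default_rng(8)
    px = rng.integers(0, 8, size=(6, 7))
    p = GLCMParams(levels=8)
    m1 = glcm(GrayImage(px, levels=8), p)
    m2 = glcm(GrayImage(px[::-1].copy(), levels=8), p)
    assert glcm_contrast(m1) == pytest.approx(glcm_contrast(m2))
    assert glcm_homogeneity(m1) == pytest.approx(glcm_homogeneity(m2))


def test_texture_metrics_uniform_cube():
    cube = refl_cube(np.full((4, 4), 1023.0))
    tm = texture_metrics(cube, full_roi(cube))
    assert tm.brightness == 255.0
    assert tm.contrast == 0.0
    assert tm.homogeneity == 1.0
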