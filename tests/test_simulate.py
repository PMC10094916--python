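"""Synthetic cohort generation: step-distribution inversion, moment-exact
texture synthesis, spectral lifting and the packaged paper-cohort preset."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hyperskin.envi import default_wavelength_grid
from hyperskin.simulate import (
    CohortPreset,
    InfeasibleTargetsError,
    PatientTargets,
    StepDistribution,
    SynthesisParameterError,
    build_cohort,
    design_paper_preset,
    gray_to_cube,
    paper_preset,
    pattern_synthesize,
    solve_step_distribution,
    validate_preset,
)
from hyperskin.spectra import band_index
from hyperskin.texture import GLCMParams, brightness, cube_to_gray, glcm, \
    glcm_contrast, glcm_homogeneity


# --------------------------------------------------------------------------
# solve_step_distribution


def test_degenerate_texture_solution():
    dist = solve_step_distribution(0.0, 1.0)
    assert dist.support.tolist() == [0]
    assert dist.probs.tolist() == [1.0]


def test_forced_unit_step_solution():
    dist = solve_step_distribution(1.0, 0.5)
    assert dist.p_zero == pytest.approx(0.0, abs=1e-12)
    assert dist.magnitude_probs()[1] == pytest.approx(1.0)


def test_documented_three_level_solution():
    """(5.86, 0.56) solves on support {0, ±1, ±8}."""
    dist = solve_step_distribution(5.86, 0.56)
    mags = dist.magnitude_probs()
    assert set(mags) <= {1, 8}
    assert dist.p_zero == pytest.approx(0.18225, abs=1e-4)
    assert mags[1] == pytest.approx(0.737714, abs=1e-4)
    assert mags[8] == pytest.approx(0.080036, abs=1e-4)
    assert dist.contrast() == pytest.approx(5.86, abs=1e-9)
    assert dist.homogeneity() == pytest.approx(0.56, abs=1e-9)


def test_infeasible_pairs_error():
    with pytest.raises(InfeasibleTargetsError):
        solve_step_distribution(0.0, 0.5)  # zero contrast forces homogeneity 1
    with pytest.raises(InfeasibleTargetsError):
        solve_step_distribution(0.1, 0.5)  # contrast < 2*(1-h)
    with pytest.raises(InfeasibleTargetsError):
        solve_step_distribution(5.0, 1.5)  # homogeneity out of range


@given(st.integers(0, 10_000))
def test_forward_inverse_consistency(seed):
    """Random feasible pairs are recovered to 1e-9 by forward evaluation."""
    rng = np.random.default_rng(seed)
    m2 = int(rng.integers(2, 17))
    p = rng.dirichlet([1.0, 1.0, 1.0])
    ref = StepDistribution(
        np.array([-m2, -1, 0, 1, m2]),
        np.array([p[2] / 2, p[1] / 2, p[0], p[1] / 2, p[2] / 2]),
    )
    c, h = ref.contrast(), ref.homogeneity()
    solved = solve_step_distribution(c, h)
    assert solved.contrast() == pytest.approx(c, abs=1e-9)
    assert solved.homogeneity() == pytest.approx(h, abs=1e-9)


def test_step_distribution_invariants_enforced():
    with pytest.raises(ValueError, match="symmetric"):
        StepDistribution(np.array([-1, 1]), np.array([0.3, 0.7]))
    with pytest.raises(ValueError, match="sum"):
        StepDistribution(np.array([0]), np.array([0.5]))


# --------------------------------------------------------------------------
# pattern_synthesize


def test_delta_distribution_gives_constant_image():
    dist = solve_step_distribution(0.0, 1.0)
    img = pattern_synthesize(143.0, dist, shape=(8, 8), seed=1)
    assert np.all(img.pixels == 143)
    m = glcm(img, GLCMParams())
    assert glcm_contrast(m) == 0.0
    assert glcm_homogeneity(m) == 1.0


@pytest.mark.parametrize("targets,bright", [
    ((5.86, 0.56), 143.33),
    ((1.0, 0.5), 80.0),
    ((2.5, 0.72), 200.0),
])
def test_synthesis_hits_moment_targets(targets, bright):
    c, h = targets
    dist = solve_step_distribution(c, h)
    img = pattern_synthesize(bright, dist, shape=(64, 64), seed=5)
    assert abs(brightness(img) - bright) <= 0.5
    m = glcm(img, GLCMParams())
    # measured moments equal the rounded-multiset moments: within the
    # multiset rounding resolution of the requested targets
    assert glcm_contrast(m) == pytest.approx(c, abs=0.05)
    assert glcm_homogeneity(m) == pytest.approx(h, abs=0.01)


def test_measured_stats_equal_realised_multiset_exactly():
    dist = solve_step_distribution(5.86, 0.56)
    img = pattern_synthesize(143.33, dist, shape=(32, 32), seed=2)
    diffs = np.abs(np.diff(img.pixels, axis=1)).ravel()
    n = diffs.size
    expected_contrast = float(np.sum(diffs.astype(float) ** 2)) / n
    expected_homog = float(np.sum(1.0 / (1.0 + diffs))) / n
    m = glcm(img, GLCMParams())
    assert glcm_contrast(m) == pytest.approx(expected_contrast, abs=1e-12)
    assert glcm_homogeneity(m) == pytest.approx(expected_homog, abs=1e-12)


def test_seeds_vary_image_not_statistics():
    dist = solve_step_distribution(3.0, 0.6)
    img1 = pattern_synthesize(120.0, dist, shape=(32, 32), seed=1)
    img2 = pattern_synthesize(120.0, dist, shape=(32, 32), seed=2)
    assert not np.array_equal(img1.pixels, img2.pixels)
    for a, b in [(img1, img2)]:
        ma, mb = glcm(a, GLCMParams()), glcm(b, GLCMParams())
        assert glcm_contrast(ma) == pytest.approx(glcm_contrast(mb), abs=1e-12)
        assert glcm_homogeneity(ma) == pytest.approx(glcm_homogeneity(mb), abs=1e-12)
        assert brightness(a) == pytest.approx(brightness(b), abs=1.0)


def test_corridor_violation_raises():
    dist = solve_step_distribution(50.0, 0.6)  # needs large steps
    with pytest.raises(SynthesisParameterError):
        pattern_synthesize(2.0, dist, shape=(8, 8), seed=0)


# --------------------------------------------------------------------------
# gray_to_cube


def test_constant_image_exact_band_target():
    dist = solve_step_distribution(0.0, 1.0)
    img = pattern_synthesize(140.0, dist, shape=(8, 8), seed=0)
    wl = default_wavelength_grid(204)
    cube = gray_to_cube(img, 854.0, wl)
    k = band_index(wl, 654.0)
    assert cube.data[:, :, k].mean() == pytest.approx(854.0, abs=1e-9)
    # all pixel spectra identical
    assert np.ptp(cube.data, axis=(0, 1)).max() == pytest.approx(0.0, abs=1e-9)


def test_brighter_gray_is_pointwise_brighter_spectrum():
    rng = np.random.default_rng(4)
    from hyperskin.texture import GrayImage

    px = rng.integers(50, 200, size=(6, 6))
    img = GrayImage(px, levels=256)
    cube = gray_to_cube(img, 700.0, default_wavelength_grid(204))
    flat = cube.data.reshape(-1, 204)
    order = np.argsort(px.ravel())
    sorted_spectra = flat[order]
    assert np.all(np.diff(sorted_spectra, axis=0) >= -1e-9)


def test_gray_cube_gray_roundtrip():
    dist = solve_step_distribution(4.0, 0.55)
    img = pattern_synthesize(150.0, dist, shape=(16, 16), seed=9)
    cube = gray_to_cube(img, 880.0, default_wavelength_grid(204))
    from hyperskin.envi import ROI

    back = cube_to_gray(cube, ROI(0, 0, 16, 16))
    assert np.abs(back.pixels - img.pixels).max() <= 1


def test_reflectance_target_out_of_range():
    from hyperskin.texture import GrayImage

    img = GrayImage(np.full((4, 4), 100), levels=256)
    with pytest.raises(SynthesisParameterError):
        gray_to_cube(img, 2000.0, default_wavelength_grid(204))


# --------------------------------------------------------------------------
# paper preset and cohort building


def test_designed_preset_satisfies_all_constraints():
    preset = design_paper_preset()
    validate_preset(preset)  # raises on any violation
    assert len(preset.patients) == 12


def test_designed_preset_matches_frozen_table():
    designed = design_paper_preset()
    frozen = paper_preset()
    for d, f in zip(designed.patients, frozen.patients):
        assert d.patient_id == f.patient_id
        for col in CohortPreset._COLUMNS[1:]:
            assert getattr(d, col) == pytest.approx(getattr(f, col), abs=1e-6)


def test_negating_differences_flips_direction_counts():
    preset = paper_preset()
    before = np.array([p.brightness_b for p in preset.patients])
    after = np.array([p.brightness_a for p in preset.patients])
    d = after - before
    assert (d > 0).sum() == ((-d) < 0).sum()
    assert (d < 0).sum() == ((-d) > 0).sum()


def test_frozen_preset_text_is_stable():
    assert paper_preset().to_text() == CohortPreset.from_text(
        paper_preset().to_text()).to_text()


def test_preset_file_roundtrip(tmp_path, tiny_preset):
    path = tmp_path / "tiny.csv"
    tiny_preset.save(path)
    back = CohortPreset.load(path)
    assert back.name == "tiny"
    assert back.rows == 24 and back.bands == 204
    assert back.patients == tiny_preset.patients


def test_build_cohort_deterministic(tmp_path, tiny_preset):
    d1, d2 = tmp_path / "c1", tmp_path / "c2"
    build_cohort(tiny_preset, d1)
    build_cohort(tiny_preset, d2)
    for f1 in sorted(d1.iterdir()):
        f2 = d2 / f1.name
        if f1.suffix in (".hdr", ".raw"):
            assert f1.read_bytes() == f2.read_bytes(), f1.name


def test_build_cohort_closed_loop(tmp_path, tiny_preset):
    from hyperskin.pipeline import analyze_manifest

    manifest = build_cohort(tiny_preset, tmp_path)
    result = analyze_manifest(manifest)
    targets = {p.patient_id: p for p in tiny_preset.patients}
    for rec in result.records:
        t = targets[rec.patient_id]
        assert rec.before.brightness == pytest.approx(t.brightness_b, abs=0.5)
        assert rec.after.brightness == pytest.approx(t.brightness_a, abs=0.5)
        assert rec.before.contrast == pytest.approx(t.contrast_b, rel=0.05)
        assert rec.after.contrast == pytest.approx(t.contrast_a, rel=0.05)
        assert rec.before.homogeneity == pytest.approx(t.homogeneity_b, abs=0.01)
        assert rec.after.homogeneity == pytest.approx(t.homogeneity_a, abs=0.01)
        assert rec.before_band.mean_cu == pytest.approx(t.refl654_b, abs=1.0)
        assert rec.after_band.mean_cu == pytest.approx(t.refl654_a, abs=1.0)


def test_noise_robust_direction_counts(tmp_path):
    """With 2 c.u. additive noise the cohort direction counts are unchanged."""
    from hyperskin.pipeline import analyze_manifest

    preset = paper_preset()
    preset.rows = preset.cols = 32  # smaller cubes keep this quick
    manifest = build_cohort(preset, tmp_path, noise_sd_cu=2.0)
    summary = analyze_manifest(manifest).summary
    assert summary.metrics["brightness"].n_increase == 9
    assert summary.metrics["contrast"].n_decrease == 10
    assert summary.metrics["homogeneity"].n_increase == 8
    assert summary.metrics["refl_mean"].n_increase == 12


def test_patient_targets_range_validation():
    with pytest.raises(ValueError):
        PatientTargets("X", 300.0, 100.0, 1.0, 1.0, 0.5, 0.5, 800.0, 800.0)
    with pytest.raises(ValueError):
        PatientTargets("X", 100.0, 100.0, 1.0, 1.0, 0.0, 0.5, 800.0, 800.0)
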