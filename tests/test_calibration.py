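"""Valid-pixel masking, highlight selection, goodness and end-to-end calibration."""

import numpy as np
import pytest

from specalib import (
    CameraModel,
    ConfigurationError,
    DegenerateInputError,
    ExposureSeries,
    HighlightSelection,
    NoHighlightsError,
    NoiseModel,
    SpectralCube,
    ValidityThresholds,
    angular_error,
    calibrate,
    compute_valid_mask,
    estimate_illuminant,
    goodness,
    lightness,
    make_noiseless_highlight_scene,
    make_surgical_scene,
    select_exposure,
    select_highlight_pixels,
)
from specalib.scenes import generate_exposure_series, generate_scene


def cube_from_pixels(pixels, exposure=10.0):
    """(n, bands) pixel list -> 1 x n x bands cube."""
    return SpectralCube(np.asarray(pixels, float)[None, :, :], exposure_ms=exposure)


class TestValidMask:
    def test_all_in_range(self):
        cube = SpectralCube(np.full((3, 3, 4), 500.0))
        assert compute_valid_mask(cube, ValidityThresholds(30, 950)).all()

    def test_single_saturated_band_invalidates_pixel(self):
        data = np.full((2, 2, 3), 500.0)
        data[0, 1, 2] = 960.0
        mask = compute_valid_mask(SpectralCube(data), ValidityThresholds(30, 950))
        assert not mask[0, 1] and mask.sum() == 3

    def test_toy_enumeration(self):
        cube = cube_from_pixels([[100, 960], [500, 500]])
        mask = compute_valid_mask(cube, ValidityThresholds(30, 950))
        np.testing.assert_array_equal(mask[0], [False, True])

    def test_bounds_are_strict(self):
        cube = cube_from_pixels([[30, 950], [31, 949]])
        mask = compute_valid_mask(cube, ValidityThresholds(30, 950))
        np.testing.assert_array_equal(mask[0], [False, True])

    def test_threshold_invariant(self):
        with pytest.raises(ConfigurationError):
            ValidityThresholds(i_min=950, i_max=950)


class TestHighlightSelection:
    def test_argmax_for_single_pixel(self):
        light = np.array([[1.0, 5.0], [3.0, 2.0]])
        sel = select_highlight_pixels(light, np.ones_like(light, bool), n_p=1)
        np.testing.assert_array_equal(sel.indices, [[0, 1]])

    def test_clamps_when_fewer_valid_than_requested(self):
        light = np.arange(6.0).reshape(2, 3)
        mask = np.zeros((2, 3), bool)
        mask[0, :] = True
        sel = select_highlight_pixels(light, mask, n_p=100)
        assert len(sel) == 3

    def test_tie_break_row_then_column(self):
        light = np.array([[5.0, 9.0], [9.0, 1.0]])
        sel = select_highlight_pixels(light, np.ones_like(light, bool), n_p=2)
        np.testing.assert_array_equal(sel.indices, [[0, 1], [1, 0]])

    def test_no_valid_pixels_raises(self):
        with pytest.raises(NoHighlightsError):
            select_highlight_pixels(np.ones((2, 2)), np.zeros((2, 2), bool), n_p=5)

    def test_selection_subset_of_mask(self, rng):
        light = rng.uniform(0, 1, (20, 20))
        mask = rng.uniform(0, 1, (20, 20)) > 0.5
        sel = select_highlight_pixels(light, mask, n_p=30)
        assert mask[sel.indices[:, 0], sel.indices[:, 1]].all()
        # ordered by descending lightness
        assert np.all(np.diff(sel.lightness_values) <= 0)


class TestEstimateIlluminant:
    def test_scaled_copies_recover_exactly(self):
        L = np.array([3.0, 1.0, 4.0, 2.0])
        cube = cube_from_pixels([c * L for c in (0.5, 1.0, 7.0)])
        sel = select_highlight_pixels(lightness(cube), np.ones((1, 3), bool), n_p=3)
        est = estimate_illuminant(cube, sel)
        np.testing.assert_allclose(est.values, L / L.sum(), atol=1e-12)

    def test_two_complementary_pixels(self):
        cube = cube_from_pixels([[1, 0], [0, 1]])
        sel = select_highlight_pixels(lightness(cube), np.ones((1, 2), bool), n_p=2)
        np.testing.assert_allclose(estimate_illuminant(cube, sel).values, [0.5, 0.5])

    def test_zero_pixel_rejected(self):
        cube = cube_from_pixels([[0, 0], [1, 1]])
        sel = HighlightSelection(
            indices=np.array([[0, 0]]), n_p=1, lightness_values=np.array([0.0])
        )
        with pytest.raises(DegenerateInputError):
            estimate_illuminant(cube, sel)

    def test_pure_specular_scene_recovers_machine_precision(
        self, grid, camera, illuminants, band_truths
    ):
        """Noise off, quantization off, no dark: pixels are scaled copies of
        the band-integrated illuminant, so recovery is exact."""
        cam = CameraModel(
            dark_offset_counts=0.0, dark_rate_counts_per_ms=0.0, read_noise_std_counts=0.0
        )
        scene = make_surgical_scene(
            illuminants["ls3_fluorescent"], grid, cam, rng=np.random.default_rng(0),
            shape=(48, 48), photon_scale=1.0, specular_peak=1e9,  # diffuse term negligible
            noise=NoiseModel(0.0),
        )
        cube, truth = generate_scene(scene, 40.0, rng=1, quantize=False)
        mask = cube.data.sum(axis=2) > 1.0
        sel = select_highlight_pixels(lightness(cube), mask, n_p=100)
        est = estimate_illuminant(cube, sel)
        assert angular_error(est, truth.illuminant_bands) < 1e-6


class TestGoodness:
    def test_hand_value(self):
        sel = HighlightSelection(
            indices=np.array([[0, 0], [0, 1], [0, 2]]),
            n_p=3,
            lightness_values=np.array([110.0, 210.0, 310.0]),
        )
        assert goodness(sel, dark_lightness_mean=10.0) == pytest.approx(20.0)

    def test_zero_when_lightness_equals_dark(self):
        sel = HighlightSelection(
            indices=np.array([[0, 0]]), n_p=1, lightness_values=np.array([10.0])
        )
        assert goodness(sel, 10.0) == 0.0

    def test_ratio_scale_invariance(self):
        sel = lambda scale: HighlightSelection(  # noqa: E731
            indices=np.array([[0, 0], [0, 1]]),
            n_p=2,
            lightness_values=scale * np.array([50.0, 90.0]),
        )
        assert goodness(sel(1.0), 5.0) == pytest.approx(goodness(sel(3.0), 15.0))

    def test_requires_positive_dark(self):
        sel = HighlightSelection(
            indices=np.array([[0, 0]]), n_p=1, lightness_values=np.array([10.0])
        )
        with pytest.raises(ConfigurationError):
            goodness(sel, 0.0)


def series_of_cubes(cubes, exposures, dark_mean=None, dark_std=None):
    n = len(cubes)
    return ExposureSeries(
        entries=tuple((t, c) for t, c in zip(exposures, cubes)),
        dark_lightness_mean=np.asarray(dark_mean if dark_mean is not None else [1.0] * n, float),
        dark_lightness_std=np.asarray(dark_std if dark_std is not None else [0.0] * n, float),
    )


class TestSelectExposure:
    def test_single_entry(self):
        cube = cube_from_pixels([[100, 100]])
        best, _ = select_exposure(series_of_cubes([cube], [10.0]))
        assert best == 10.0

    def test_constructed_profile_argmax(self):
        # lightness 60/130/90 with dark mean 10 -> G = 5, 12, 8
        cubes = [cube_from_pixels([[v, v]]) for v in (60.0, 130.0, 90.0)]
        best, profile = select_exposure(
            series_of_cubes(cubes, [10.0, 20.0, 30.0], dark_mean=[10.0] * 3)
        )
        assert best == 20.0
        np.testing.assert_allclose(profile.values, [5.0, 12.0, 8.0])

    def test_fully_saturated_exposures_excluded(self):
        valid = cube_from_pixels([[100, 100]])
        saturated = cube_from_pixels([[1000, 1000]])
        best, profile = select_exposure(series_of_cubes([valid, saturated], [10.0, 20.0]))
        assert best == 10.0
        assert profile.values[1] == -np.inf

    def test_all_saturated_raises(self):
        saturated = cube_from_pixels([[1000, 1000]])
        with pytest.raises(NoHighlightsError):
            select_exposure(series_of_cubes([saturated], [10.0]))

    def test_tie_prefers_shorter_exposure(self):
        cube = cube_from_pixels([[100, 100]])
        best, _ = select_exposure(series_of_cubes([cube, cube], [10.0, 20.0]))
        assert best == 10.0


class TestCalibrate:
    def test_identical_cubes_match_single_cube_path(self):
        cube = cube_from_pixels([[100, 300], [40, 40]])
        single = calibrate(series_of_cubes([cube], [10.0]))
        triple = calibrate(series_of_cubes([cube] * 3, [10.0, 20.0, 30.0],
                                           dark_mean=[1.0] * 3, dark_std=[0.0] * 3))
        np.testing.assert_allclose(single.illuminant.values, triple.illuminant.values)

    def test_estimate_invariant_to_global_scaling(self):
        data = np.array([[[100.0, 300.0], [40.0, 40.0]]])
        a = calibrate(series_of_cubes([SpectralCube(data)], [10.0]))
        b = calibrate(series_of_cubes([SpectralCube(data * 1.5)], [10.0]))
        np.testing.assert_allclose(a.illuminant.values, b.illuminant.values, atol=1e-12)

    def test_noiseless_series_recovers_truth(self, grid, camera, illuminants, band_truths):
        scene = make_noiseless_highlight_scene(
            illuminants["ls2_halogen"], grid, camera, rng=np.random.default_rng(3),
            shape=(64, 64),
        )
        series, truth = generate_exposure_series(
            scene, exposures=np.arange(5.0, 80.0, 10.0), rng=4
        )
        result = calibrate(series)
        assert angular_error(result.illuminant, truth.illuminant_bands) < 0.1

    def test_error_decreases_with_specular_contrast(self, grid, camera, illuminants):
        """More specular-dominant highlights give a better estimate (noise off)."""
        errs = []
        for peak in (2.0, 20.0, 200.0):
            scene = make_surgical_scene(
                illuminants["ls3_fluorescent"], grid, camera.noiseless(),
                rng=np.random.default_rng(11), shape=(64, 64),
                specular_peak=peak, noise=NoiseModel(0.0),
            )
            series, truth = generate_exposure_series(
                scene, exposures=np.arange(5.0, 80.0, 10.0), rng=12
            )
            result = calibrate(series)
            errs.append(angular_error(result.illuminant, truth.illuminant_bands))
        assert errs[0] >= errs[1] >= errs[2]

    def test_selected_exposure_below_first_fully_saturating(self, grid, camera, illuminants):
        scene = make_surgical_scene(
            illuminants["ls1_xenon"], grid, camera, rng=np.random.default_rng(5),
            shape=(64, 64),
        )
        series, _ = generate_exposure_series(scene, rng=6)
        result = calibrate(series)
        profile = result.goodness_profile
        saturated = profile.exposures[~np.isfinite(profile.values)]
        if saturated.size:
            assert result.exposure_ms < saturated.min()
        # chosen exposure must be in the low-exposure regime of the sweep
        assert result.exposure_ms <= 50.0
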