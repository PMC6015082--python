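"""Degradation-spot counting, index normalization, and line-scan profiles."""

import numpy as np
import pytest
from scipy import ndimage

from endopolar import (
    average_profiles,
    degradation_index,
    detect_degradation_spots,
    extract_linescan,
    normalize_linescan,
)
from endopolar.collagenolysis import LineScanProfile, auto_references
from endopolar.errors import (
    EmptySampleError,
    GeometryError,
    NormalizationError,
    ValidationError,
)
from endopolar.synthetic import _splat_points, generate_linescan_scene


class TestDetectDegradationSpots:
    def test_blank_field_counts_zero(self):
        _, n = detect_degradation_spots(np.full((64, 64), 100.0))
        assert n == 0

    def test_forty_separated_spots_counted_exactly(self, rng):
        sigma = 2.0
        # 40 spots on an 8x5 grid, jittered below half the grid pitch
        gx, gy = np.meshgrid(np.arange(8) * 30 + 20, np.arange(5) * 30 + 20)
        xs = gx.ravel() + rng.uniform(-4, 4, 40)
        ys = gy.ravel() + rng.uniform(-4, 4, 40)
        img = np.zeros((180, 280))
        _splat_points(img, xs, ys, 600 * 2 * np.pi * sigma**2)
        img = ndimage.gaussian_filter(img, sigma) + 100
        img = rng.poisson(img).astype(float)
        _, n = detect_degradation_spots(img, sigma)
        assert n == 40

    def test_intensity_doubling_leaves_count_unchanged(self, rng):
        sigma = 2.0
        img = np.zeros((96, 96))
        _splat_points(img, np.array([20.0, 70.0]), np.array([30.0, 60.0]),
                      600 * 2 * np.pi * sigma**2)
        img = ndimage.gaussian_filter(img, sigma) + 100
        _, n1 = detect_degradation_spots(img, sigma)
        _, n2 = detect_degradation_spots(2.0 * img, sigma)
        assert n1 == n2 == 2

    def test_additive_offset_with_corrected_threshold(self):
        sigma = 2.0
        img = np.zeros((96, 96))
        _splat_points(img, np.array([48.0]), np.array([48.0]),
                      600 * 2 * np.pi * sigma**2)
        img = ndimage.gaussian_filter(img, sigma)
        # LoG response is offset-free, so the same absolute threshold works
        _, n1 = detect_degradation_spots(img, sigma, threshold=50.0)
        _, n2 = detect_degradation_spots(img + 500.0, sigma, threshold=50.0)
        assert n1 == n2 == 1


class TestDegradationIndex:
    def test_control_mean_is_one_hundred_by_construction(self):
        table = degradation_index([30, 40, 50], [5, 5, 5], [True, True, True])
        assert table.norm_index.mean() == pytest.approx(100.0)

    def test_zero_spot_field_has_zero_index(self):
        table = degradation_index([40, 0], [5, 5], [True, False])
        assert table.norm_index.iloc[1] == 0.0

    def test_doubling_counts_preserves_control_normalization(self):
        t1 = degradation_index([30, 40, 12], [5, 5, 5], [True, True, False])
        t2 = degradation_index([60, 80, 24], [5, 5, 5], [True, True, False])
        np.testing.assert_allclose(t2.raw_index, 2 * t1.raw_index)
        np.testing.assert_allclose(t2.norm_index, t1.norm_index)
        assert t2[t2.is_control].norm_index.mean() == pytest.approx(100.0)

    def test_degenerate_control_rejected(self):
        with pytest.raises(NormalizationError):
            degradation_index([10], [5], [False])
        with pytest.raises(NormalizationError):
            degradation_index([0, 10], [5, 5], [True, False])


class TestLineScan:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((50, 80), 7.0)
        prof = extract_linescan(img, np.array([[5.0, 20.0], [70.0, 20.0]]), 1.0)
        np.testing.assert_allclose(prof.intensities["intensity"], 7.0)

    def test_single_bright_pixel_peaks_at_its_arclength(self):
        img = np.zeros((40, 100))
        img[20, 60] = 1000.0
        prof = extract_linescan(img, np.array([[0.0, 20.0], [99.0, 20.0]]), 1.0)
        s_peak = prof.positions_um[np.argmax(prof.intensities["intensity"])]
        assert s_peak == pytest.approx(60.0, abs=1.0)

    def test_transverse_width_takes_maximum_off_axis(self):
        img = np.zeros((40, 100))
        img[24, 50] = 1000.0  # 4 px off the scan line
        line = np.array([[0.0, 20.0], [99.0, 20.0]])
        on_axis = extract_linescan(img, line, 1.0).intensities["intensity"]
        wide = extract_linescan(img, line, 1.0, transverse_width_um=10.0)
        assert on_axis.max() < 500.0
        assert wide.intensities["intensity"].max() > 900.0

    def test_polyline_outside_image_rejected(self):
        img = np.zeros((40, 40))
        with pytest.raises(GeometryError):
            extract_linescan(img, np.array([[0.0, 0.0], [100.0, 0.0]]), 1.0)

    def test_anterior_bump_position_matches_generator_truth(self):
        images, truth = generate_linescan_scene(seed=5)
        row_um = truth["axis_row"] * 0.5
        line = np.array([[0.0, row_um], [59.5, row_um]])
        prof = extract_linescan(images, line, 0.5, transverse_width_um=4.0)
        s_peak = prof.positions_um[np.argmax(prof.intensities["degradation"])]
        assert s_peak == pytest.approx(truth["bump_um"], abs=0.5)

    def test_auto_references_track_the_dapi_ridge(self):
        images, truth = generate_linescan_scene(seed=6)
        row_um = truth["axis_row"] * 0.5
        line = np.array([[0.0, row_um], [59.5, row_um]])
        prof = extract_linescan(images, line, 0.5, transverse_width_um=4.0)
        back, center, front = auto_references(prof)
        assert back < center < front
        assert center == pytest.approx(truth["nucleus_center_um"], abs=2.0)


class TestNormalizeLinescan:
    def _profile(self):
        pos = np.linspace(0.0, 60.0, 121)
        return LineScanProfile(pos, {"v": pos.copy()})

    def test_references_map_exactly_to_minus_one_zero_one(self):
        prof = self._profile()
        norm = normalize_linescan(prof, (5.0, 25.0, 55.0))
        # intensity equals position, so reading the curve at -1, 0, 1
        # recovers the reference coordinates exactly
        for coord, expected in [(-1.0, 5.0), (0.0, 25.0), (1.0, 55.0)]:
            i = np.argmin(np.abs(norm.grid - coord))
            assert norm.grid[i] == pytest.approx(coord, abs=1e-12)
            assert norm.intensities["v"][i] == pytest.approx(expected, abs=1e-9)

    def test_midpoint_between_center_and_front_maps_to_half(self):
        norm = normalize_linescan(self._profile(), (5.0, 25.0, 55.0))
        i = np.argmin(np.abs(norm.grid - 0.5))
        assert norm.intensities["v"][i] == pytest.approx(40.0, abs=1e-9)

    def test_symmetric_references_give_affine_map(self):
        # center equidistant: the two segments share one slope
        norm = normalize_linescan(self._profile(), (10.0, 30.0, 50.0))
        # closed-form affine: s = 30 + 20 * coord
        np.testing.assert_allclose(
            norm.intensities["v"], 30.0 + 20.0 * norm.grid, atol=1e-9
        )

    def test_normalization_idempotent_on_normalized_coordinates(self):
        pos = np.linspace(-1.0, 1.0, 201)
        prof = LineScanProfile(pos, {"v": np.sin(pos * 3)})
        norm = normalize_linescan(prof, (-1.0, 0.0, 1.0))
        np.testing.assert_allclose(norm.intensities["v"], prof.intensities["v"],
                                   atol=1e-12)

    def test_disordered_references_rejected(self):
        with pytest.raises(ValidationError):
            normalize_linescan(self._profile(), (25.0, 5.0, 55.0))


class TestAverageProfiles:
    def test_identical_curves_have_zero_sd(self):
        c = np.linspace(0, 1, 11)
        out = average_profiles([c, c.copy()])
        np.testing.assert_allclose(out["mean"], c)
        np.testing.assert_allclose(out["sd"], 0.0)
        assert (out["n"] == 2).all()

    def test_single_curve_flagged_n_one_with_zero_sd(self):
        c = np.linspace(0, 1, 11)
        out = average_profiles([c])
        assert (out["n"] == 1).all()
        np.testing.assert_allclose(out["sd"], 0.0)

    def test_three_curves_match_direct_arithmetic(self):
        curves = [np.array([0.0, 1.0, 2.0]), np.array([2.0, 3.0, 4.0]),
                  np.array([4.0, 5.0, 9.0])]
        out = average_profiles(curves)
        np.testing.assert_allclose(out["mean"], [2.0, 3.0, 5.0])
        np.testing.assert_allclose(out["sd"], np.std(curves, axis=0, ddof=1))

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySampleError):
            average_profiles([])
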