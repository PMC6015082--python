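"""Shape scoring, centrosome geometry, Tks5 area, invasion, ablation."""

import numpy as np
import pytest
from scipy import ndimage

from endopolar import (
    NucleusTrack,
    ablation_displacement,
    centrosome_ahead_fraction,
    centrosome_nucleus_distance,
    compute_kinematics,
    invasion_index,
    score_nucleus_shape,
    tks5_area_ratio,
)
from endopolar.errors import EmptySampleError, ValidationError
from endopolar.synthetic import (
    SceneParams,
    _stamp_disk,
    generate_nucleus_population,
    generate_scene,
)


def _disk_mask(shape=(96, 96), cy=48.0, cx=48.0, radius=30.0):
    mask = np.zeros(shape, dtype=bool)
    _stamp_disk(mask, cx, cy, radius, True)
    return mask


class TestShapeScoring:
    def test_disk_is_circular_and_normal(self):
        d = score_nucleus_shape(_disk_mask())
        assert 0.95 <= d.circularity <= 1.05
        assert d.solidity > 0.97
        assert d.lobe_count == 0
        assert d.deformation_class == "normal"

    def test_peanut_template_is_deformed(self):
        masks, labels = generate_nucleus_population(10, 1.0, seed=2)
        for m in masks:
            d = score_nucleus_shape(m)
            assert d.deformation_class == "deformed"
            assert d.lobe_count >= 2 or d.solidity < 0.92

    def test_labeled_population_fraction_recovered(self):
        masks, labels = generate_nucleus_population(60, 0.3, seed=8)
        pred = np.array(
            [score_nucleus_shape(m).deformation_class == "deformed" for m in masks]
        )
        assert abs(pred.mean() - labels.mean()) <= 0.05

    def test_empty_and_split_masks_rejected(self):
        with pytest.raises(ValidationError):
            score_nucleus_shape(np.zeros((10, 10), dtype=bool))
        two = np.zeros((30, 30), dtype=bool)
        two[2:6, 2:6] = True
        two[20:24, 20:24] = True
        with pytest.raises(ValidationError):
            score_nucleus_shape(two)

    def test_descriptors_rotation_invariant_within_discretization(self):
        from endopolar.synthetic import _stamp_ellipse

        mask = np.zeros((160, 160), dtype=bool)
        _stamp_ellipse(mask, 80.0, 80.0, 35.0, axis_ratio=1.5,
                       orientation_deg=15.0, value=True)
        rot = np.zeros((160, 160), dtype=bool)
        _stamp_ellipse(rot, 80.0, 80.0, 35.0, axis_ratio=1.5,
                       orientation_deg=60.0, value=True)
        d0 = score_nucleus_shape(mask)
        d1 = score_nucleus_shape(rot)
        assert d1.circularity == pytest.approx(d0.circularity, rel=0.02)
        assert d1.solidity == pytest.approx(d0.solidity, rel=0.02)
        assert d0.deformation_class == d1.deformation_class == "normal"


class TestCentrosomeDistance:
    def test_point_on_boundary_is_zero(self):
        mask = _disk_mask(radius=20.0)
        assert centrosome_nucleus_distance((68.0, 48.0), mask, 1.0) == 0.0

    def test_point_outside_disk_edge(self):
        mask = _disk_mask(radius=20.0)
        # 5 px beyond the rim along +x, 0.2 um pixels -> 1.0 um
        d = centrosome_nucleus_distance((73.0 * 0.2, 48.0 * 0.2), mask, 0.2)
        assert d == pytest.approx(1.0, abs=0.5 * 0.2)

    def test_matches_brute_force_boundary_scan(self, rng):
        mask = _disk_mask(radius=18.0)
        boundary = mask & ~ndimage.binary_erosion(mask)
        rr, cc = np.nonzero(boundary)
        for _ in range(20):
            x, y = rng.uniform(0, 95, 2)
            got = centrosome_nucleus_distance((x, y), mask, 1.0)
            r, c = int(round(y)), int(round(x))
            inside = mask[r, c] if (0 <= r < 96 and 0 <= c < 96) else False
            expected = 0.0 if inside else float(np.hypot(cc - x, rr - y).min())
            assert got == pytest.approx(expected, abs=1e-6)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            centrosome_nucleus_distance((0.0, 0.0), np.zeros((5, 5), bool), 1.0)


def _track_and_masks(n_frames=6, step=3.0, radius=10.0, shape=(128, 128)):
    pos = np.column_stack(
        [20.0 + step * np.arange(n_frames), np.full(n_frames, 60.0)]
    )
    track = NucleusTrack(0, np.arange(n_frames), pos, np.ones(n_frames))
    compute_kinematics(track, frame_interval_min=5.0)
    masks = []
    for p in pos:
        m = np.zeros(shape, dtype=bool)
        _stamp_disk(m, p[0], p[1], radius, True)  # pixel_size 1.0
        masks.append(m)
    return track, pos, masks


class TestAheadFraction:
    def test_centrosome_beyond_front_every_frame_is_100(self):
        track, pos, masks = _track_and_masks()
        centro = pos + np.array([15.0, 0.0])  # beyond the 10 um radius, +x
        assert centrosome_ahead_fraction(track, centro, masks, 1.0) == 100.0

    def test_centrosome_at_centroid_is_0(self):
        track, pos, masks = _track_and_masks()
        assert centrosome_ahead_fraction(track, pos, masks, 1.0) == 0.0

    def test_bernoulli_parameter_recovered_from_scene_truth(self):
        params = SceneParams(
            n_cells=6, n_frames=25, image_shape=(1024, 1024),
            centrosome_ahead_prob=0.5, seed=21,
        )
        truth = generate_scene(params)
        flags, percents = [], []
        for cell in range(params.n_cells):
            track = NucleusTrack(
                cell, np.arange(params.n_frames), truth.centroids_um[cell],
                np.ones(params.n_frames),
            )
            compute_kinematics(track, params.frame_interval)
            masks = [truth.cell_mask(cell, t) for t in range(params.n_frames)]
            percents.append(
                centrosome_ahead_fraction(
                    track, truth.centrosomes_um[cell], masks, params.pixel_size
                )
            )
            flags.append(truth.centrosome_ahead[cell, :-1].mean() * 100)
        # scoring reproduces the generator's own flags frame-exactly
        np.testing.assert_allclose(percents, flags, atol=1e-9)

    def test_stationary_track_has_no_scored_frames(self):
        pos = np.tile([[50.0, 50.0]], (4, 1))
        track = NucleusTrack(0, np.arange(4), pos, np.ones(4))
        compute_kinematics(track, 5.0, min_displacement_um=0.5)
        masks = [_disk_mask(radius=10.0)] * 4
        with pytest.raises(EmptySampleError):
            centrosome_ahead_fraction(track, pos, masks, 1.0)


class TestTks5Area:
    def _cell(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5:45, 5:30] = True  # 1000 px cell
        return mask

    def test_blank_channel_is_zero_percent(self):
        assert tks5_area_ratio(np.full((50, 50), 10.0), self._cell()) == 0.0

    def test_seven_pixel_region_excluded_by_8px_rule(self):
        img = np.full((50, 50), 10.0)
        img[10, 10:17] = 200.0  # 7-px region
        assert tks5_area_ratio(img, self._cell()) == 0.0

    def test_hundred_pixel_region_in_thousand_pixel_cell_is_ten_percent(self):
        img = np.full((50, 50), 10.0)
        img[10:20, 10:20] = 200.0  # 100 px
        assert tks5_area_ratio(img, self._cell()) == pytest.approx(10.0)

    def test_monotone_in_region_size_above_cutoff(self):
        ratios = []
        for w in [8, 12, 20, 30]:
            img = np.full((50, 50), 10.0)
            img[10, 10 : 10 + w] = 200.0
            ratios.append(tks5_area_ratio(img, self._cell()))
        assert ratios == sorted(ratios)

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValidationError):
            tks5_area_ratio(np.zeros((5, 5)), np.zeros((5, 5), bool))


class TestInvasionIndex:
    def test_all_intensity_at_surface_is_zero(self):
        assert invasion_index([500.0, 0.0, 0.0], z_step_um=10.0) == 0.0

    def test_all_intensity_deep_is_one(self):
        assert invasion_index([0.0, 0.0, 0.0, 0.0, 400.0], z_step_um=10.0) == 1.0

    def test_hand_written_stack_fraction(self):
        # slices at 0, 20, 40 um with intensities 300, 100, 100
        assert invasion_index([300.0, 100.0, 100.0], z_step_um=20.0) == pytest.approx(0.2)

    def test_scale_invariant(self):
        a = invasion_index([300.0, 100.0, 100.0], 20.0)
        b = invasion_index([600.0, 200.0, 200.0], 20.0)
        assert a == b

    def test_first_nonzero_origin_discounts_empty_leading_slices(self):
        # two empty slices acquired above the gel shift the origin
        a = invasion_index([0.0, 0.0, 300.0, 100.0, 100.0], 20.0,
                           origin="first_nonzero")
        assert a == pytest.approx(0.2)

    def test_zero_total_rejected(self):
        with pytest.raises(EmptySampleError):
            invasion_index([0.0, 0.0], 10.0)


class TestAblation:
    def test_stationary_centrosome_is_zero_pair(self):
        w = np.tile([[5.0, 5.0]], (6, 1))
        assert ablation_displacement(w, w, 0.0) == (0.0, 0.0)

    def test_post_window_drift_along_movement_is_positive(self):
        pre = np.tile([[0.0, 0.0]], (5, 1))
        post = np.column_stack([np.linspace(0, 2.0, 5), np.zeros(5)])
        pair = ablation_displacement(pre, post, movement_direction_deg=0.0)
        assert pair == (0.0, pytest.approx(2.0))

    def test_seeded_oscillation_matches_projection_oracle(self, rng):
        direction = 37.0
        u = np.array([np.cos(np.radians(direction)), -np.sin(np.radians(direction))])
        pre = rng.normal(0, 1, (6, 2))
        post = rng.normal(0, 1, (6, 2))
        got = ablation_displacement(pre, post, direction)
        assert got[0] == pytest.approx(float((pre[-1] - pre[0]) @ u), abs=1e-9)
        assert got[1] == pytest.approx(float((post[-1] - post[0]) @ u), abs=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValidationError):
            ablation_displacement([[0.0, 0.0]], [[0.0, 0.0], [1.0, 0.0]], 0.0)
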