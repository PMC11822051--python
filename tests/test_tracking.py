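"""Track metrics, nucleus detection, linking, and filtering rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from collmig.simulate import RenderConfig, SimulationConfig, render_nuclei_frames, simulate_monolayer
from collmig.tracking import (
    Detection,
    Track,
    detect_nuclei,
    filter_tracks,
    link_tracks,
    median_speed,
    orientation_angle,
    straightness_index,
)


def make_track(points, dt_min=10.0):
    pts = np.asarray(points, dtype=float)
    frames = np.arange(len(pts))
    return Track(0, frames, frames * dt_min, pts[:, 0], pts[:, 1])


class TestStraightness:
    def test_collinear_equally_spaced_is_exactly_one(self):
        track = make_track([(i, 0) for i in range(5)])
        assert straightness_index(track) == 1.0

    def test_out_and_back_is_exactly_zero(self):
        track = make_track([(0, 0), (5, 0), (0, 0)])
        assert straightness_index(track) == 0.0

    def test_three_four_five_triangle(self):
        track = make_track([(0, 0), (3, 0), (3, 4)])
        assert straightness_index(track) == pytest.approx(5.0 / 7.0)

    def test_stationary_track_is_undefined(self):
        track = make_track([(2, 2), (2, 2), (2, 2)])
        assert straightness_index(track) is None

    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.01, 100),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_invariant_under_rotation_translation_scaling(self, angle, scale, tx, ty):
        pts = np.array([(0, 0), (3, 1), (5, -2), (4, 4), (1, 3)], dtype=float)
        base = straightness_index(make_track(pts))
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = scale * pts @ R.T + (tx, ty)
        assert straightness_index(make_track(moved)) == pytest.approx(base, rel=1e-9)

    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=12))
    def test_bounded_by_one(self, points):
        s = straightness_index(make_track(points))
        if s is not None:
            assert 0.0 <= s <= 1.0 + 1e-12


class TestMedianSpeed:
    def test_uniform_steps_unit_conversion(self):
        # 3.6 um per 10-min step = 3600 nm / 600 s = 6 nm/s
        track = make_track([(i * 3.6, 0) for i in range(4)])
        assert median_speed(track) == pytest.approx(6.0)

    def test_stationary_is_zero(self):
        track = make_track([(1, 1)] * 5)
        assert median_speed(track) == 0.0

    def test_median_is_robust_to_one_huge_step(self):
        track = make_track([(0, 0), (1, 0), (3, 0), (103, 0)])
        # steps 1, 2, 100 um per 10 min: median 2 um / 10 min
        assert median_speed(track) == pytest.approx(2.0 * 1000.0 / 600.0)

    def test_window_restricts_steps(self):
        track = make_track([(0, 0), (1, 0), (10, 0)])
        assert median_speed(track, window_min=(0, 10)) == pytest.approx(1000.0 / 600.0)


class TestOrientationAngle:
    def test_along_inward_normal_is_zero(self):
        assert orientation_angle(np.array([2.0, 0.0])) == pytest.approx(0.0)

    def test_directly_away_is_180(self):
        assert orientation_angle(np.array([-2.0, 0.0])) == pytest.approx(180.0)

    def test_plus_y_image_coords_is_plus_90(self):
        # y points down in image coordinates
        assert orientation_angle(np.array([0.0, 1.0])) == pytest.approx(90.0)

    def test_folded_discards_sign(self):
        assert orientation_angle(np.array([1.0, -1.0])) == pytest.approx(-45.0)
        assert orientation_angle(np.array([1.0, -1.0]), folded=True) == pytest.approx(45.0)

    def test_zero_displacement_is_undefined(self):
        assert orientation_angle(np.zeros(2)) is None


class TestFilterTracks:
    def test_three_step_track_excluded_four_step_kept(self):
        t3 = make_track([(i, 0) for i in range(4)])  # 3 steps
        t4 = make_track([(i, 0) for i in range(5)])  # 4 steps
        kept = filter_tracks([t3, t4])
        assert [t.n_steps for t in kept] == [4]

    def test_truncation_shortens_to_frames_before_cutoff(self):
        t = make_track([(i, 0) for i in range(15)])
        kept = filter_tracks([t], truncation_frame=10)
        assert len(kept) == 1 and len(kept[0].frames) == 10
        assert kept[0].frames.max() == 9

    def test_truncation_can_remove_short_remainder(self):
        t = make_track([(i, 0) for i in range(15)])
        assert filter_tracks([t], truncation_frame=3) == []


class TestDetectNuclei:
    def test_single_spot_recovered_subpixel(self):
        rc = RenderConfig(pixel_size=1.0, image_width=64, image_height=64,
                          nucleus_sigma=2.0, noise_sigma=0.0, background_level=10,
                          signal_level=200, bit_depth=16)
        track = Track(0, np.array([0]), np.array([0.0]), np.array([30.4]), np.array([22.7]))
        frame = render_nuclei_frames([track], rc)[0]
        dets = detect_nuclei(frame, sigma_um=2.0, pixel_size=1.0, threshold=5.0)
        assert len(dets) == 1
        assert abs(dets[0].x_um - 30.4) < 0.25
        assert abs(dets[0].y_um - 22.7) < 0.25

    def test_blank_frame_yields_no_detections(self):
        assert detect_nuclei(np.zeros((64, 64)), 2.0, 1.0, 1.0) == []

    def test_two_spots_four_sigma_apart_resolved(self):
        rc = RenderConfig(pixel_size=1.0, image_width=64, image_height=64,
                          nucleus_sigma=2.0, noise_sigma=0.0, background_level=10,
                          signal_level=200, bit_depth=16)
        tracks = [
            Track(0, np.array([0]), np.array([0.0]), np.array([28.0]), np.array([32.0])),
            Track(1, np.array([0]), np.array([0.0]), np.array([36.0]), np.array([32.0])),
        ]
        frame = render_nuclei_frames(tracks, rc)[0]
        dets = detect_nuclei(frame, sigma_um=2.0, pixel_size=1.0, threshold=5.0)
        assert len(dets) == 2


class TestLinkTracks:
    def _dets(self, per_frame):
        return [[Detection(f, x, y) for x, y in pts] for f, pts in enumerate(per_frame)]

    def test_two_stationary_spots_give_two_full_tracks(self):
        dets = self._dets([[(0, 0), (50, 50)]] * 10)
        tracks = link_tracks(dets, max_displacement_um=10.0, frame_interval_min=10.0)
        assert len(tracks) == 2
        assert all(len(t.frames) == 10 for t in tracks)

    def test_jump_beyond_max_displacement_splits_track(self):
        dets = self._dets([[(0, 0)], [(1, 0)], [(40, 0)], [(41, 0)]])
        tracks = link_tracks(dets, max_displacement_um=10.0, frame_interval_min=10.0)
        assert sorted(len(t.frames) for t in tracks) == [2, 2]

    def test_simulator_correspondence_at_wide_spacing(self):
        """Linking ground-truth positions of a sparse simulated monolayer
        recovers at least 95% of the true frame-to-frame links."""
        cfg = SimulationConfig(n_cells=60, box_width=800, box_height=500,
                               wound_half_width=60, speed_v0=5.0,
                               alignment_strength=0.3, heading_noise=0.6,
                               wound_bias=0.2, n_steps=12, seed=4,
                               min_spacing=16.0)
        truth = simulate_monolayer(cfg)
        # detections carry the true identity through their list order
        per_frame = []
        for f in range(cfg.n_steps + 1):
            per_frame.append(
                [Detection(f, t.x_um[f], t.y_um[f]) for t in truth]
            )
        tracks = link_tracks(per_frame, max_displacement_um=10.0, frame_interval_min=10.0)
        # a link is correct when both endpoints belong to the same true cell
        correct = total = 0
        for tr in tracks:
            for k in range(tr.n_steps):
                f0, f1 = tr.frames[k], tr.frames[k + 1]
                p0 = np.array([tr.x_um[k], tr.y_um[k]])
                p1 = np.array([tr.x_um[k + 1], tr.y_um[k + 1]])
                id0 = min(range(len(truth)), key=lambda i: np.hypot(
                    truth[i].x_um[f0] - p0[0], truth[i].y_um[f0] - p0[1]))
                id1 = min(range(len(truth)), key=lambda i: np.hypot(
                    truth[i].x_um[f1] - p1[0], truth[i].y_um[f1] - p1[1]))
                total += 1
                correct += id0 == id1
        assert total >= 60 * 12 * 0.9
        assert correct / total >= 0.95


class TestMetricRecoveryFromSimulator:
    def test_aligned_noiseless_cells_move_straight_at_configured_speed(self):
        """With full alignment, zero noise, and a common initial heading the
        model reduces to rigid parallel translation: straightness 1 and
        median speed equal to the configured self-propulsion speed, for
        every cell that never reflects off the domain boundary."""
        cfg = SimulationConfig(n_cells=70, box_width=1400, box_height=500,
                               wound_half_width=60, speed_v0=5.0,
                               alignment_strength=1.0, heading_noise=0.0,
                               wound_bias=0.0, n_steps=10, seed=7,
                               initial_heading=0.0, min_spacing=12.0)
        tracks = simulate_monolayer(cfg)
        # keep clear of the right wall: reflections there flip headings and
        # the flip propagates one interaction radius per step via alignment
        margin = cfg.step_um * cfg.n_steps + cfg.n_steps * cfg.interaction_radius
        interior = [t for t in tracks if t.x_um[0] < cfg.box_width - margin - 70.0]
        assert len(interior) >= 30
        for t in interior:
            assert straightness_index(t) == pytest.approx(1.0, abs=1e-9)
            assert median_speed(t) == pytest.approx(5.0, rel=0.02)
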