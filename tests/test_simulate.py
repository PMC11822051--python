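"""Active-particle monolayer model and the forward renderers."""

import numpy as np
import pytest

from collmig.fieldstats import order_parameter, velocity_field_from_tracks
from collmig.simulate import (
    RenderConfig,
    SimulationConfig,
    make_blob_image,
    make_gp_pair,
    render_nuclei_frames,
    render_texture_frames,
    simulate_monolayer,
)
from collmig.tracking import Track


def small_config(**kw):
    base = dict(n_cells=80, box_width=300, box_height=200, wound_half_width=50,
                speed_v0=5.0, dt=10.0, n_steps=10, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulationConfig:
    def test_rejects_nonfinite_and_out_of_range(self):
        with pytest.raises(ValueError):
            small_config(speed_v0=float("nan"))
        with pytest.raises(ValueError):
            small_config(alignment_strength=1.5)
        with pytest.raises(ValueError):
            small_config(wound_bias=-0.1)
        with pytest.raises(ValueError):
            small_config(box_width=0.0)
        with pytest.raises(ValueError):
            # stripe must fit inside the box
            small_config(wound_half_width=200.0)

    def test_step_length_units(self):
        # 5 nm/s for 10 min = 3 um
        assert small_config().step_um == pytest.approx(3.0)


class TestSimulateMonolayer:
    def test_deterministic_for_identical_config(self):
        cfg = small_config(seed=17)
        a, b = simulate_monolayer(cfg), simulate_monolayer(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.x_um, y.x_um)
            assert np.array_equal(x.y_um, y.y_um)

    def test_mass_conservation(self):
        tracks = simulate_monolayer(small_config())
        assert len(tracks) == 80
        assert all(len(t.frames) == 11 for t in tracks)

    def test_uncoupled_noisy_cells_have_no_polar_order(self):
        cfg = small_config(alignment_strength=0.0, wound_bias=0.0,
                           heading_noise=2.5, n_cells=200,
                           box_width=600, box_height=400, n_steps=6)
        tracks = simulate_monolayer(cfg)
        f = velocity_field_from_tracks(tracks, 3, 40.0, (600, 400))
        assert order_parameter(f) < 0.25

    def test_full_alignment_with_common_heading_is_rigid_translation(self):
        cfg = small_config(alignment_strength=1.0, heading_noise=0.0,
                           wound_bias=0.0, initial_heading=0.5,
                           box_width=800, box_height=500, n_steps=5,
                           n_cells=100, min_spacing=10.0)
        tracks = simulate_monolayer(cfg)
        step = cfg.step_um
        travel = step * cfg.n_steps
        # wall reflections flip headings and, with full alignment, the flip
        # propagates one interaction radius per step: keep clear of the
        # walls the motion points at by travel + n_steps * radius
        margin = travel + cfg.n_steps * cfg.interaction_radius
        interior = [
            t for t in tracks
            if t.x_um[0] < 800 - margin and t.y_um[0] < 500 - margin
        ]
        assert len(interior) >= 25
        for t in interior:
            dx = np.diff(t.x_um)
            dy = np.diff(t.y_um)
            assert np.allclose(dx, step * np.cos(0.5), atol=1e-9)
            assert np.allclose(dy, step * np.sin(0.5), atol=1e-9)
        f = velocity_field_from_tracks(interior, 2, 40.0, (800, 500))
        assert order_parameter(f) == pytest.approx(1.0)

    def test_order_parameter_nondecreasing_in_alignment(self):
        """Stochastic monotonicity: the seed-mean polar order grows with
        the alignment strength."""
        means = []
        for alpha in (0.0, 0.5, 1.0):
            ops = []
            for seed in range(10):
                cfg = small_config(alignment_strength=alpha, wound_bias=0.0,
                                   heading_noise=0.8, seed=seed,
                                   n_cells=150, box_width=400, box_height=300,
                                   n_steps=8)
                tracks = simulate_monolayer(cfg)
                f = velocity_field_from_tracks(tracks, 6, 30.0, (400, 300))
                ops.append(order_parameter(f))
            means.append(np.mean(ops))
        assert means[0] < means[1] < means[2]

    def test_initial_positions_avoid_the_wound_stripe(self):
        cfg = small_config()
        tracks = simulate_monolayer(cfg)
        x0 = np.array([t.x_um[0] for t in tracks])
        assert not np.any((x0 > 100.0) & (x0 < 200.0))


class TestRenderNuclei:
    RC = RenderConfig(pixel_size=1.0, image_width=64, image_height=48,
                      nucleus_sigma=2.0, background_level=10,
                      signal_level=200, noise_sigma=0.0, bit_depth=16)

    @staticmethod
    def still(x, y, n_frames=3):
        frames = np.arange(n_frames)
        return Track(0, frames, frames * 10.0, np.full(n_frames, x), np.full(n_frames, y))

    def test_stationary_cell_frames_identical_with_peak_at_position(self):
        stack = render_nuclei_frames([self.still(30.0, 20.0)], self.RC)
        assert np.array_equal(stack[0], stack[1]) and np.array_equal(stack[1], stack[2])
        peak = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert peak == (20, 30)

    def test_two_cells_give_two_local_maxima(self):
        t2 = Track(1, np.arange(3), np.arange(3) * 10.0,
                   np.full(3, 40.0), np.full(3, 20.0))
        frame = render_nuclei_frames([self.still(30.0, 20.0), t2], self.RC)[0]
        assert frame[20, 30] > frame[20, 35] and frame[20, 40] > frame[20, 35]

    def test_noise_free_centroid_matches_ground_truth(self):
        stack = render_nuclei_frames([self.still(30.6, 20.3)], self.RC)
        img = stack[0].astype(float) - 10.0
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        cx = (xx * img).sum() / img.sum()
        cy = (yy * img).sum() / img.sum()
        assert abs(cx - 30.6) < 0.25 and abs(cy - 20.3) < 0.25


class TestRenderTexture:
    RC = RenderConfig(pixel_size=1.0, image_width=128, image_height=96,
                      cell_radius=9.0, background_level=20, signal_level=200,
                      noise_sigma=0.0, bit_depth=16)

    def test_wound_stripe_has_lower_variance_than_sheet(self):
        cfg = small_config(n_cells=120, n_steps=1)
        tracks = simulate_monolayer(cfg)
        rc = RenderConfig(pixel_size=2.0, image_width=150, image_height=100,
                          noise_sigma=2.0)
        frame = render_texture_frames(tracks, rc, seed=1)[0].astype(float)
        stripe = frame[:, 55:95]  # x in (110, 190) um; stripe is (100, 200)
        sheet = frame[:, 5:45]
        assert stripe.std() < 0.2 * sheet.std()

    def test_rigid_integer_translation_shifts_the_frame(self):
        frames = np.arange(3)
        # 2 px per frame along +x, constant fractional part
        tr = Track(0, frames, frames * 10.0, 40.0 + 2.0 * frames, np.full(3, 48.0))
        stack = render_texture_frames([tr], self.RC, seed=2).astype(float)
        shifted = np.roll(stack[0], 2, axis=1)
        # compare away from the image border
        assert np.array_equal(stack[1][:, 5:-5], shifted[:, 5:-5])

    def test_empty_track_set_renders_pure_background(self):
        stack = render_texture_frames([], self.RC, seed=3)
        assert stack.shape == (1, 96, 128)
        assert np.all(stack == 20)


class TestMakeGPPair:
    def test_zero_gp_with_unit_g_gives_equal_channels(self):
        a, b = make_gp_pair(np.zeros((8, 8)), 100.0, G=1.0)
        assert np.array_equal(a, b)

    def test_half_gp_splits_75_25(self):
        a, b = make_gp_pair(np.full((4, 4), 0.5), 100.0, G=1.0)
        assert np.allclose(a, 75.0) and np.allclose(b, 25.0)

    def test_out_of_range_gp_rejected(self):
        with pytest.raises(ValueError):
            make_gp_pair(np.full((2, 2), 1.0), 100.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            make_gp_pair(np.zeros((2, 2)), 0.0)


class TestMakeBlobImage:
    def test_count_above_threshold_matches_construction(self):
        _, truth = make_blob_image([0.3, 1.0], pixel_size=0.1, seed=0)
        assert truth.count_above(0.5) == 1

    def test_empty_request_gives_blank_count_zero(self):
        img, truth = make_blob_image([], pixel_size=0.1, noise_sigma=0.0, seed=0)
        assert truth.count_above(0.0) == 0
        assert np.allclose(img, 10.0)

    def test_exact_threshold_not_counted_under_strict_greater(self):
        _, truth = make_blob_image([0.5, 0.5], pixel_size=0.1, seed=0)
        assert truth.count_above(0.5) == 0

    def test_overcrowded_request_rejected(self):
        with pytest.raises(ValueError, match="over-crowded"):
            make_blob_image([50.0] * 60, pixel_size=0.1, image_shape=(80, 80), seed=0)
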