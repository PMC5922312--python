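"""Tracker: frame ops, backgrounds, blob rules, reflections, whole videos."""

import numpy as np
import pytest

import welltrack as wt
from welltrack import tracker as tk


class TestNormalize:
    def test_constant_frame_maps_to_ones(self):
        out = tk.normalize_frame(np.full((4, 4), 137.0))
        assert np.allclose(out, 1.0)

    def test_two_pixel_example(self):
        assert np.allclose(tk.normalize_frame(np.array([[1.0, 3.0]])),
                           [[0.5, 1.5]])

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0.1, 5.0, (30, 40))
        assert abs(tk.normalize_frame(frame).mean() - 1.0) < 1e-9

    def test_zero_frame_rejected(self):
        with pytest.raises(ValueError):
            tk.normalize_frame(np.zeros((3, 3)))


class TestSmooth:
    def test_sigma_zero_is_identity(self):
        frame = np.random.default_rng(1).random((10, 10))
        assert np.array_equal(tk.smooth_frame(frame, 0.0), frame)

    def test_impulse_response_sums_to_one(self):
        frame = np.zeros((31, 31))
        frame[15, 15] = 1.0
        assert abs(tk.smooth_frame(frame, 2.0).sum() - 1.0) < 1e-6

    def test_noise_variance_shrinks(self):
        frame = np.random.default_rng(2).normal(size=(64, 64))
        assert tk.smooth_frame(frame, 1.5).var() < frame.var()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            tk.smooth_frame(np.ones((3, 3)), -1.0)


class TestBackgrounds:
    def test_static_bg_of_identical_frames(self):
        frame = np.random.default_rng(3).uniform(0.5, 1.5, (20, 20))
        video = [frame] * 7
        expected = tk.smooth_frame(tk.normalize_frame(frame), 1.0)
        assert np.allclose(tk.static_background(video), expected)

    def test_exactly_1000_equispaced_samples(self):
        idx = tk.equispaced_indices(2000, 1000)
        assert len(idx) == 1000
        assert idx[0] == 0 and idx[-1] == 1999
        assert np.all(np.diff(idx) >= 1)

    def test_short_video_uses_all_frames(self):
        assert np.array_equal(tk.equispaced_indices(500, 1000),
                              np.arange(500))

    def test_dynamic_bg_mean_of_available(self):
        frames = [np.full((2, 2), v) for v in (1.0, 3.0)]
        assert np.allclose(tk.dynamic_background(frames), 2.0)

    def test_dynamic_bg_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            tk.dynamic_background([])


def _scene(blob_value, size=6, prev=None, dyn_delta=None):
    """A 20x20 normalized scene with one dark blob vs flat backgrounds."""
    bg = np.ones((20, 20))
    frame = bg.copy()
    ys, xs = np.unravel_index(range(size), (2, size // 2 + 1))
    for k in range(size):
        frame[8 + ys[k], 8 + xs[k]] = blob_value
    dyn = frame.copy() if dyn_delta is None else bg.copy()
    return frame, bg, dyn


class TestBlobRules:
    def test_no_difference_no_blobs(self):
        bg = np.ones((10, 10))
        assert tk.detect_candidate_blobs(bg, bg, bg, None) == []

    def test_single_pixel_blob_rejected(self):
        frame = np.ones((10, 10))
        frame[5, 5] = 0.2   # diff -0.8, but size 1
        bg = np.ones((10, 10))
        assert tk.detect_candidate_blobs(frame, bg, bg.copy(), None) == []

    def test_stale_static_blob_needs_previous_overlap(self):
        # blob visible against the static background only (stationary for
        # more than 5 frames): accepted iff rule (a) holds
        frame, bg, _ = _scene(0.4)
        dyn = frame.copy()          # dynamic background contains the larva
        assert tk.detect_candidate_blobs(frame, bg, dyn, None) == []
        prev = np.zeros_like(frame, dtype=bool)
        prev[8, 8] = True
        blobs = tk.detect_candidate_blobs(frame, bg, dyn, prev)
        assert len(blobs) == 1 and blobs[0].cond_prev

    def test_moving_blob_accepted_via_dynamic_rule(self):
        frame, bg, _ = _scene(0.4)
        dyn = bg.copy()             # larva absent from recent frames
        blobs = tk.detect_candidate_blobs(frame, bg, dyn, None)
        assert len(blobs) == 1 and blobs[0].cond_moving

    def test_anchor_is_most_contrasted_pixel(self):
        bg = np.ones((10, 10))
        frame = bg.copy()
        frame[4, 4:7] = (0.45, 0.1, 0.3)
        blobs = tk.detect_candidate_blobs(frame, bg, bg.copy(), None,
                                          threshold=-0.5)
        # all three pixels pass the threshold; anchor at the -0.9 pixel
        assert len(blobs) == 1
        assert blobs[0].anchor == (5, 4)
        assert blobs[0].min_diff == pytest.approx(-0.9)


def _blob(size, dist, angle_deg, center=(0.0, 0.0)):
    ang = np.radians(angle_deg)
    x = center[0] + dist * np.cos(ang)
    y = center[1] + dist * np.sin(ang)
    pix = np.tile([int(x), int(y)], (size, 1))
    return tk.Blob(pixels=pix, min_diff=-1.0, anchor=(x, y))


class TestReflectionRemoval:
    def test_single_blob_unchanged(self):
        blobs = [_blob(5, 20, 0)]
        assert tk.remove_reflections(blobs, (0, 0)) == blobs

    def test_smaller_outer_aligned_blob_removed(self):
        larva = _blob(10, 20, 0)
        refl = _blob(4, 28, 5)
        kept = tk.remove_reflections([larva, refl], (0, 0))
        assert kept == [larva]

    def test_wide_angle_keeps_both(self):
        larva = _blob(10, 20, 0)
        other = _blob(4, 28, 15)
        assert len(tk.remove_reflections([larva, other], (0, 0))) == 2

    def test_largest_blob_never_removed(self):
        rng = np.random.default_rng(4)
        blobs = [_blob(int(s), float(d), float(a))
                 for s, d, a in zip(rng.integers(2, 12, 6),
                                    rng.uniform(5, 30, 6),
                                    rng.uniform(0, 360, 6))]
        kept = tk.remove_reflections(blobs, (0, 0))
        biggest = max(blobs, key=lambda b: b.size)
        assert biggest in kept


class TestSelectPosition:
    def test_empty_gives_gap(self):
        assert tk.select_position([]) is None

    def test_highest_contrast_wins(self):
        b1 = _blob(5, 10, 0)
        b1.min_diff = -0.9
        b2 = _blob(5, 12, 90)
        b2.min_diff = -0.6
        assert tk.select_position([b2, b1]) is b1


def _mini_video(n_frames, blob_frames, pos_by_frame, h=40, w=40, depth=0.9):
    """Flat-background video with a 2x2 blob at given frames/positions."""
    video = np.ones((n_frames, h, w))
    for t in blob_frames:
        x, y = pos_by_frame(t)
        video[t, y: y + 2, x: x + 2] = 1.0 - depth
    return video


class TestTrackWell:
    def test_gap_then_resume_on_movement(self):
        # visible 0-9 at A, hidden 10-39, reappears at B from frame 40:
        # the reappearance is movement evidence (rule (b)) and resumes
        n = 60
        video = _mini_video(
            n, list(range(10)) + list(range(40, 60)),
            lambda t: (10, 10) if t < 10 else (25, 25))
        traj = tk.track_well(video, center=(20.0, 20.0), radius=15.0,
                             well_id=0, cfg=tk.TrackerConfig(sigma=0.0))
        gaps = traj.gap_mask
        assert not gaps[: 10].any()
        assert gaps[10: 40].all()
        assert not gaps[40:].any()
        assert np.allclose(traj.positions[45], (25, 25), atol=2)

    def test_permanently_static_object_is_never_tracked(self):
        # an object present in every frame belongs to the static
        # background and yields no blob at all
        video = _mini_video(50, range(50), lambda t: (15, 15))
        traj = tk.track_well(video, center=(20.0, 20.0), radius=15.0,
                             well_id=0, cfg=tk.TrackerConfig(sigma=0.0))
        assert traj.gap_mask.all()

    def test_illumination_doubling_leaves_detections_unchanged(self):
        video = _mini_video(30, range(30),
                            lambda t: (8 + (t % 10), 20))
        cfg = tk.TrackerConfig(sigma=0.0)
        t1 = tk.track_well(video, (20.0, 20.0), 15.0, 0, cfg)
        t2 = tk.track_well(video * 2.0, (20.0, 20.0), 15.0, 0, cfg)
        assert np.array_equal(t1.positions, t2.positions, equal_nan=True)


class TestTrackVideo:
    def test_positions_match_ground_truth(self, truth500, tracked500):
        true = truth500.positions_array()
        pos = np.stack([t.positions for t in tracked500], axis=1)
        err = np.hypot(*(pos - true).transpose(2, 0, 1))
        hit = np.nan_to_num(err, nan=np.inf) <= 2.0
        assert hit.mean() >= 0.95

    def test_rmse_below_1_5px(self, truth500, tracked500):
        true = truth500.positions_array()
        pos = np.stack([t.positions for t in tracked500], axis=1)
        err = np.hypot(*(pos - true).transpose(2, 0, 1))
        assert np.sqrt(np.nanmean(err ** 2)) < 1.5

    def test_positions_stay_within_well_neighborhood(self, plate24,
                                                     tracked500):
        for traj in tracked500:
            pos = traj.positions[~traj.gap_mask]
            d = np.hypot(*(pos - np.asarray(traj.center)).T)
            assert (d <= 1.2 * plate24.radius).all()

    def test_determinism(self, plate24, render500):
        again = wt.track_video(render500.frames, plate24)
        for a, b in zip(again, wt.track_video(render500.frames, plate24)):
            assert np.array_equal(a.positions, b.positions, equal_nan=True)

    def test_empty_well_gives_all_gaps(self):
        wells = wt.make_plate(2, radius=20.0, spacing_factor=2.5)
        video = np.ones((30, *wells.image_shape)) * 0.8
        trajs = wt.track_video(video, wells)
        assert all(t.gap_mask.all() for t in trajs)

    def test_shape_mismatch_rejected(self, plate24):
        with pytest.raises(ValueError, match="shape"):
            wt.track_video(np.ones((3, 10, 10)), plate24)


class TestTrajectory:
    def test_filled_positions_carry_last_known(self):
        pos = np.array([[np.nan, np.nan], [1.0, 2.0], [np.nan, np.nan],
                        [3.0, 4.0]])
        traj = tk.Trajectory(0, pos, 25.0, (0.0, 0.0), 10.0)
        filled = traj.filled_positions()
        assert np.allclose(filled, [[1, 2], [1, 2], [1, 2], [3, 4]])

    def test_all_gap_rejected(self):
        traj = tk.Trajectory(0, np.full((5, 2), np.nan), 25.0,
                             (0.0, 0.0), 10.0)
        with pytest.raises(ValueError):
            traj.filled_positions()
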