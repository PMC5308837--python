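"""Detection, linking, and biased-random-walk statistics."""

import numpy as np
import pytest

from chiralswim import (
    ImageStack,
    OpticsModel,
    Track,
    detect_cells,
    link_tracks,
    persistence_autocorrelation,
    population_summary,
    render_stack,
    subtract_background,
    track_stack,
    track_statistics,
)


def _gaussian_spot(shape, cx, cy, amp=1000.0, sigma=2.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def _stack(frames):
    arr = np.clip(np.rint(np.asarray(frames)), 0, 65535).astype(np.uint16)
    return ImageStack(frames=arr, optics=OpticsModel(image_size=arr.shape[1:],
                                                     pixel_size=1.0, frame_rate=1.0))


class TestBackgroundSubtraction:
    def test_static_scene_goes_to_zero(self):
        frame = _gaussian_spot((64, 64), 30, 30) + 100
        stack = _stack([frame, frame, frame])
        out = subtract_background(stack)
        assert np.all(out.frames == 0)

    def test_moving_spot_keeps_signal_loses_background(self):
        frames = [100 + _gaussian_spot((64, 64), 10 + 15 * i, 30) for i in range(3)]
        out = subtract_background(_stack(frames))
        # brute-force per-pixel min oracle
        raw = np.stack([np.clip(np.rint(f), 0, 65535) for f in frames])
        oracle = raw - raw.min(axis=0)
        assert np.array_equal(out.frames, oracle.astype(np.uint16))
        assert out.frames[0, 30, 10] > 800

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(_stack([np.zeros((8, 8))]))


class TestDetection:
    def test_blank_frame_gives_no_detections(self):
        assert len(detect_cells(np.zeros((64, 64)))) == 0

    def test_two_separated_spots_found_at_centres(self):
        frame = _gaussian_spot((64, 64), 20, 32) + _gaussian_spot((64, 64), 40, 32)
        dets = detect_cells(frame)
        assert len(dets) == 2
        xs = sorted(d[0] for d in dets)
        assert xs[0] == pytest.approx(20, abs=1)
        assert xs[1] == pytest.approx(40, abs=1)

    def test_nearby_spots_merge_after_blur(self):
        frame = _gaussian_spot((64, 64), 31, 32) + _gaussian_spot((64, 64), 32, 32)
        dets = detect_cells(frame, blur_sigma=2.0)
        assert len(dets) == 1


class TestLinking:
    def test_single_moving_cell_yields_one_track(self):
        dets = [np.array([[10.0 + 2 * f, 20.0]]) for f in range(10)]
        tracks = link_tracks(dets)
        assert len(tracks) == 1
        assert tracks[0].n_points == 10

    def test_jump_beyond_max_link_splits_track(self):
        dets = [np.array([[10.0, 10.0]]), np.array([[12.0, 10.0]]),
                np.array([[40.0, 10.0]]), np.array([[42.0, 10.0]])]
        tracks = link_tracks(dets, max_link=15.0)
        assert len(tracks) == 2
        assert [t.n_points for t in tracks] == [2, 2]

    def test_crossing_cells_keep_identity_via_prediction(self):
        # cell A moves right at 4 px/frame, cell B moves left at 4 px/frame,
        # crossing at frame 2; prediction must keep identities straight
        a = [(0.0 + 4 * f, 10.0) for f in range(5)]
        b = [(16.0 - 4 * f, 10.0) for f in range(5)]
        dets = [np.array([a[f], b[f]]) for f in range(5)]
        tracks = link_tracks(dets)
        assert len(tracks) == 2
        ends = sorted((t.x[0], t.x[-1]) for t in tracks)
        assert ends[0] == (0.0, 16.0)  # A kept moving right
        assert ends[1] == (16.0, 0.0)  # B kept moving left

    def test_linking_invariant_to_detection_order(self, rng):
        frames = []
        paths = [
            [(5.0 + 2.5 * f, 8.0 + 1.0 * f) for f in range(8)],
            [(40.0 - 2.0 * f, 30.0) for f in range(8)],
            [(20.0, 5.0 + 3.0 * f) for f in range(8)],
        ]
        for f in range(8):
            pts = np.array([p[f] for p in paths])
            frames.append(pts)
        base = link_tracks(frames)
        shuffled = [f[rng.permutation(len(f))] for f in frames]
        other = link_tracks(shuffled)
        key = lambda t: (t.x[0], t.y[0])
        for t1, t2 in zip(sorted(base, key=key), sorted(other, key=key)):
            assert np.array_equal(t1.x, t2.x)
            assert np.array_equal(t1.y, t2.y)

    def test_pixel_and_time_scaling(self):
        dets = [np.array([[10.0 + 2 * f, 0.0]]) for f in range(6)]
        tracks = link_tracks(dets, pixel_size=0.65, frame_rate=5.0)
        t = tracks[0]
        assert t.frame_interval == pytest.approx(0.2)
        assert t.x[1] - t.x[0] == pytest.approx(2 * 0.65)


class TestTrackStatistics:
    def test_uniform_straight_motion(self):
        times = np.arange(0, 20, 0.2)
        trk = Track(times=times, x=5.0 * times, y=np.zeros_like(times))
        st = track_statistics(trk, eval_dt=2.0)
        assert st.mean_speed == pytest.approx(5.0)
        assert st.persistence == pytest.approx(1.0)

    def test_periodic_reversal_gives_minus_one(self):
        # square-wave displacement with period 2δt: velocity flips sign
        # every window
        dt = 2.0
        times = np.arange(0, 24, dt)
        x = np.array([0.0, 1.0] * (len(times) // 2))[: len(times)]
        trk = Track(times=times, x=x, y=np.zeros_like(times))
        st = track_statistics(trk, eval_dt=dt)
        assert st.persistence == pytest.approx(-1.0)

    def test_circular_motion_persistence_is_cos_omega_dt(self):
        w = 0.5
        times = np.arange(0, 40, 0.2)
        trk = Track(times=times, x=10 * np.cos(w * times), y=10 * np.sin(w * times))
        st = track_statistics(trk, eval_dt=2.0)
        assert st.persistence == pytest.approx(np.cos(w * 2.0), abs=1e-9)

    def test_short_tracks_excluded(self):
        times = np.arange(0, 4.0, 0.2)  # < 5 s
        trk = Track(times=times, x=times, y=times)
        assert track_statistics(trk, eval_dt=2.0, min_duration=5.0) is None

    def test_persistence_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        times = np.arange(0, 30, 0.2)
        x = np.cumsum(rng.normal(1.0, 0.5, len(times)))
        y = np.cumsum(rng.normal(0.2, 0.5, len(times)))
        base = track_statistics(Track(times=times, x=x, y=y), eval_dt=2.0)
        for theta, dx, dy in [(0.7, 5.0, -3.0), (2.9, -11.0, 40.0)]:
            xr = np.cos(theta) * x - np.sin(theta) * y + dx
            yr = np.sin(theta) * x + np.cos(theta) * y + dy
            st = track_statistics(Track(times=times, x=xr, y=yr), eval_dt=2.0)
            assert st.persistence == pytest.approx(base.persistence, abs=1e-12)
            assert st.mean_speed == pytest.approx(base.mean_speed, abs=1e-12)


class TestPopulationSummary:
    def _track(self, duration, speed=6.0, angle=0.0, tid=0):
        times = np.arange(0, duration + 0.1, 0.2)
        return Track(times=times, x=speed * np.cos(angle) * times,
                     y=speed * np.sin(angle) * times, track_id=tid)

    def test_single_track_returns_its_own_statistics(self):
        trk = self._track(10.0)
        s = population_summary([trk])
        assert s.n_tracks == 1
        assert s.mean_speed == pytest.approx(6.0)
        assert s.mean_persistence == pytest.approx(1.0)

    def test_duration_weighted_mean(self):
        # persistence 1 (straight, 30 s) and ~cos(1.0)-weighted circle: use
        # straight + reversing tracks with known persistences 1 and -1
        dt = 2.0
        times10 = np.arange(0, 10.01, dt)
        x_rev = np.array([0.0, 1.0] * 10)[: len(times10)]
        reversing = Track(times=times10, x=x_rev, y=np.zeros_like(times10), track_id=1)
        straight = self._track(30.0, tid=0)
        s = population_summary([straight, reversing], eval_dt=dt)
        # weighted mean of (1, -1) with weights (30, 10)
        assert s.mean_persistence == pytest.approx((30 * 1 + 10 * -1) / 40)

    def test_threshold_fractions(self):
        straight = self._track(20.0, tid=0)
        w = 0.5
        times = np.arange(0, 20.01, 0.2)
        circle = Track(times=times, x=10 * np.cos(w * times),
                       y=10 * np.sin(w * times), track_id=1)
        s = population_summary([straight, circle])
        # circle persistence cos(1) ≈ 0.54 < 0.8; straight = 1.0
        assert s.persistence_fractions[0.80] == pytest.approx(0.5)
        assert s.persistence_fractions[0.95] == pytest.approx(0.5)

    def test_speed_conditional_persistence(self):
        fast = self._track(20.0, speed=9.0, tid=0)
        slow = self._track(20.0, speed=2.0, tid=1)
        s = population_summary([fast, slow])
        assert s.speed_conditional_persistence[5.0] == pytest.approx(1.0)
        assert np.isnan(s.speed_conditional_persistence[10.0])

    def test_empty_input_gives_explicit_empty_result(self):
        s = population_summary([])
        assert s.n_tracks == 0
        assert np.isnan(s.mean_persistence)


class TestAutocorrelation:
    def test_straight_tracks_stay_at_one(self):
        times = np.arange(0, 30, 0.2)
        tracks = [Track(times=times, x=4 * times, y=0 * times)]
        curve = persistence_autocorrelation(tracks, base_dt=0.5, lags=[0, 1, 2, 5])
        assert np.allclose(curve["autocorrelation"], 1.0, atol=1e-9)

    def test_circular_tracks_decay_as_cos_omega_lag(self):
        w = 0.4
        times = np.arange(0, 60, 0.2)
        tracks = [Track(times=times, x=10 * np.cos(w * times), y=10 * np.sin(w * times))]
        lags = [0.0, 1.0, 2.0, 4.0]
        curve = persistence_autocorrelation(tracks, base_dt=0.5, lags=lags)
        for lag, val in zip(curve["lag_s"], curve["autocorrelation"]):
            assert val == pytest.approx(np.cos(w * lag), abs=1e-9)


class TestEndToEndRecovery:
    def test_rendered_straight_swimmer_recovered(self):
        optics = OpticsModel(image_size=(160, 160), focal_plane_z=0.0)
        times = np.arange(0, 30.01, 0.2)
        pos = np.zeros((len(times), 2, 3))
        for i, y0 in enumerate((30.0, 70.0)):
            pos[:, i, 0] = 8.0 + 2.5 * times
            pos[:, i, 1] = y0
        stack = render_stack(pos, optics, trajectory_dt=0.2)
        tracks = track_stack(stack)
        summary = population_summary(tracks)
        assert summary.n_tracks == 2
        assert summary.mean_speed == pytest.approx(2.5, rel=0.05)
        assert summary.mean_persistence > 0.99

    def test_detection_falls_off_with_defocus(self):
        # the configured plateau-then-exponential detectability profile
        # must be what the detector actually sees
        optics = OpticsModel(image_size=(64, 64), focal_plane_z=0.0,
                             peak_intensity=2000.0)
        found = []
        z_offsets = np.array([0.0, 5.0, 9.0, 12.0, 15.0, 25.0, 40.0])
        for z in z_offsets:
            pos = np.tile(np.array([20.0, 20.0, z]), (3, 1, 1))
            # add a reference in-focus cell so the detection threshold
            # (set from image statistics) stays comparable across stacks
            ref = np.tile(np.array([35.0, 35.0, 0.0]), (3, 1, 1))
            stack = render_stack(
                np.concatenate([pos, ref], axis=1), optics, trajectory_dt=0.2
            )
            dets = detect_cells(stack.frames[0].astype(float) - 100.0,
                                min_prominence=100.0)
            found.append(len(dets))
        # full detection on the plateau, loss beyond it
        assert found[0] == 2 and found[1] == 2 and found[2] == 2
        assert found[-1] == 1  # deep cell lost, reference still found
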