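"""Analytical movement model: evaluation, fitting, effective shape."""

import dataclasses

import numpy as np
import pytest

from chiralswim import (
    Kymograph,
    KymographModel,
    ShapeModelParams,
    effective_shape,
    eval_model,
    fit_model,
    goodness_of_fit,
    model_kymograph,
)

TIMES_200HZ = np.arange(0, 1.0, 1 / 200)


def _make_traces(params, times=TIMES_200HZ, noise_sd=0.0, rng=None):
    traces = []
    for z in params.z:
        x, _ = eval_model(params, z, times)
        x = np.atleast_1d(x)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, len(x))
        traces.append(Kymograph(z=float(z), times=times, x=x))
    return traces


class TestEvalModel:
    def test_zero_beat_traces_a_circle(self, trypomastigote_like_params):
        p = dataclasses.replace(
            trypomastigote_like_params, A_b=np.zeros(8),
            z=trypomastigote_like_params.z.copy(),
            A_r=trypomastigote_like_params.A_r.copy(),
            p_r=trypomastigote_like_params.p_r.copy(),
            p_b=trypomastigote_like_params.p_b.copy(),
            p_o=trypomastigote_like_params.p_o.copy(),
            width=trypomastigote_like_params.width.copy(),
        )
        z = p.z[3]
        x, y = eval_model(p, z, TIMES_200HZ)
        r = np.hypot(x, y)
        assert np.allclose(r, p.A_r[3], atol=1e-12)

    def test_planar_beat_limits(self):
        z = np.linspace(0, 10, 8)
        base = dict(z=z, A_r=np.zeros(8), A_b=np.ones(8),
                    p_b=np.zeros(8), p_o=np.zeros(8), f_b=10.0, omega_r=0.0)
        p_yz = ShapeModelParams(p_r=np.zeros(8), **base)
        x, y = eval_model(p_yz, 5.0, TIMES_200HZ)
        assert np.allclose(x, 0.0, atol=1e-12)
        assert np.allclose(y, np.sin(2 * np.pi * 10.0 * TIMES_200HZ), atol=1e-9)
        p_xz = ShapeModelParams(p_r=np.full(8, np.pi / 2), **base)
        x, y = eval_model(p_xz, 5.0, TIMES_200HZ)
        assert np.allclose(y, 0.0, atol=1e-9)

    def test_magnitude_bounded_by_triangle_inequality(self):
        z = np.linspace(0, 10, 8)
        p = ShapeModelParams(
            z=z, A_r=np.ones(8), p_r=np.linspace(0, 2, 8), A_b=np.full(8, 0.5),
            p_b=np.linspace(0, 3, 8), p_o=np.full(8, 0.7),
            omega_r=7.0, f_b=13.0,
        )
        t = np.linspace(0, 5, 5000)
        x, y = eval_model(p, 4.0, t)
        r = np.hypot(x, y)
        assert np.all(r <= 1.5 + 1e-9)
        assert np.all(r >= 0.5 - 1e-9)

    def test_periodic_in_rotation_when_beat_absent(self):
        z = np.linspace(0, 10, 8)
        p = ShapeModelParams(
            z=z, A_r=np.ones(8), p_r=np.linspace(0, 2, 8), A_b=np.zeros(8),
            p_b=np.zeros(8), p_o=np.zeros(8), omega_r=5.0, f_b=13.0,
        )
        period = 2 * np.pi / 5.0
        x1, y1 = eval_model(p, 4.0, np.array([0.3, 1.1]))
        x2, y2 = eval_model(p, 4.0, np.array([0.3 + period, 1.1 + period]))
        assert np.allclose([x1, y1], [x2, y2], atol=1e-9)

    def test_z_outside_range_rejected(self, trypomastigote_like_params):
        with pytest.raises(ValueError):
            eval_model(trypomastigote_like_params, 99.0, 0.0)

    def test_apparent_beat_amplitude_oscillates_with_rotation(self):
        # slow rotation, fast beat: apparent x amplitude sweeps between
        # ~A_b (beat plane in view) and ~0 (orthogonal)
        z = np.linspace(0, 10, 8)
        p = ShapeModelParams(
            z=z, A_r=np.zeros(8), p_r=np.zeros(8), A_b=np.ones(8),
            p_b=np.zeros(8), p_o=np.zeros(8), omega_r=2 * np.pi * 0.5, f_b=20.0,
        )
        t = np.arange(0, 1.0, 1 / 400)
        x, _ = eval_model(p, 5.0, t)
        beat_window = int(400 / 20)
        amps = [np.ptp(x[i : i + beat_window]) / 2
                for i in range(0, len(x) - beat_window, beat_window)]
        assert max(amps) > 0.9
        assert min(amps) < 0.1


class TestGoodnessOfFit:
    def test_identity_is_one(self, rng):
        x = rng.normal(size=100)
        assert goodness_of_fit(x, x) == 1.0

    def test_mean_model_is_zero(self, rng):
        x = rng.normal(size=1000)
        model = np.full_like(x, x.mean())
        assert goodness_of_fit(model, x) == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_reduces_r2_by_variance_ratio(self, rng):
        t = np.linspace(0, 10, 5000)
        clean = np.sin(t)
        sigma = 0.2
        noisy = clean + rng.normal(0, sigma, len(t))
        expected = 1.0 - sigma**2 / np.var(noisy)
        assert goodness_of_fit(clean, noisy) == pytest.approx(expected, abs=0.02)

    def test_constant_observed_trace_flagged(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(5), np.ones(5))


class TestFitting:
    def test_round_trip_with_exact_start(self, trypomastigote_like_params):
        traces = _make_traces(trypomastigote_like_params)
        res = fit_model(traces, trypomastigote_like_params)
        assert res.mean_r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.params.omega_r == pytest.approx(
            trypomastigote_like_params.omega_r, rel=1e-6
        )

    def test_recovery_from_perturbed_start_with_noise(
        self, trypomastigote_like_params, rng
    ):
        p = trypomastigote_like_params
        traces = _make_traces(p, noise_sd=0.01 * float(np.std(
            np.concatenate([k.x for k in _make_traces(p)]))), rng=rng)
        start = dataclasses.replace(
            p,
            A_r=p.A_r * 1.2, A_b=p.A_b * 0.8,
            p_r=p.p_r + 0.3, p_b=p.p_b - 0.3, p_o=p.p_o * 0.8,
            omega_r=p.omega_r * 1.15, f_b=p.f_b * 0.85,
            z=p.z.copy(), width=p.width.copy(),
        )
        res = fit_model(traces, start)
        assert abs(res.params.omega_r / p.omega_r - 1) < 0.05
        assert abs(res.params.f_b / p.f_b - 1) < 0.05
        assert np.all(np.abs(res.params.A_r / p.A_r - 1) < 0.05)
        assert np.all(np.abs(res.params.A_b / p.A_b - 1) < 0.05)
        assert res.mean_r_squared > 0.99

    def test_non_rotating_cell_flagged_unidentifiable(
        self, promastigote_like_params
    ):
        traces = _make_traces(promastigote_like_params)
        with pytest.warns(UserWarning, match="not identifiable"):
            res = fit_model(traces, promastigote_like_params)
        assert not res.rotation_identifiable

    def test_summary_reports_parameters(self, trypomastigote_like_params):
        traces = _make_traces(trypomastigote_like_params)
        res = KymographModel(traces).fit(trypomastigote_like_params)
        text = res.summary()
        assert "omega_r" in text and "R^2" in text

    def test_fewer_than_two_positions_rejected(self, trypomastigote_like_params):
        traces = _make_traces(trypomastigote_like_params)[:1]
        with pytest.raises(ValueError):
            KymographModel(traces)

    def test_fitted_phases_are_continuous(self, trypomastigote_like_params, rng):
        p = trypomastigote_like_params
        traces = _make_traces(p, noise_sd=0.005, rng=rng)
        start = dataclasses.replace(
            p, omega_r=p.omega_r * 1.1, f_b=p.f_b * 0.9,
            z=p.z.copy(), A_r=p.A_r.copy(), p_r=p.p_r.copy(),
            A_b=p.A_b.copy(), p_b=p.p_b.copy(), p_o=p.p_o.copy(),
            width=p.width.copy(),
        )
        res = fit_model(traces, start)
        for ph in (res.params.p_r, res.params.p_o):
            assert np.all(np.abs(np.diff(ph)) < np.pi)


class TestModelKymograph:
    def test_trace_matches_direct_evaluation(self, trypomastigote_like_params):
        k = model_kymograph(trypomastigote_like_params, 4.0, TIMES_200HZ)
        x, _ = eval_model(trypomastigote_like_params, 4.0, TIMES_200HZ)
        assert np.array_equal(k.x, np.atleast_1d(x))
        assert k.times[1] - k.times[0] == pytest.approx(1 / 200)


class TestEffectiveShape:
    def test_linear_phase_gives_helical_centreline(self):
        z = np.linspace(0, 14, 8)
        p = ShapeModelParams(
            z=z, A_r=np.full(8, 0.8), p_r=np.linspace(0, 3 * np.pi, 8),
            A_b=np.ones(8), p_b=np.zeros(8), p_o=np.zeros(8),
            omega_r=10.0, f_b=20.0,
        )
        shape = effective_shape(p)
        r = np.hypot(shape.points[:, 0], shape.points[:, 1])
        assert np.allclose(r, 0.8, atol=1e-12)
        phases = np.unwrap(np.arctan2(shape.points[:, 0], shape.points[:, 1]))
        assert np.allclose(np.diff(phases), 3 * np.pi / 7, atol=1e-9)

    def test_constant_phase_gives_planar_centreline(self, promastigote_like_params):
        shape = effective_shape(promastigote_like_params)
        # all points share the same azimuth → planar (achiral)
        azimuth = np.arctan2(shape.points[:, 0], shape.points[:, 1])
        assert np.ptp(azimuth) < 1e-12

    def test_negating_phase_slope_mirrors_the_helix(self):
        z = np.linspace(0, 14, 8)
        kw = dict(z=z, A_r=np.full(8, 0.8), A_b=np.zeros(8), p_b=np.zeros(8),
                  p_o=np.zeros(8), omega_r=10.0, f_b=20.0)
        right = effective_shape(ShapeModelParams(p_r=np.linspace(0, 3, 8), **kw))
        left = effective_shape(ShapeModelParams(p_r=-np.linspace(0, 3, 8), **kw))
        # mirror image through the x = 0 plane
        assert np.allclose(left.points[:, 0], -right.points[:, 0], atol=1e-12)
        assert np.allclose(left.points[:, 1:], right.points[:, 1:], atol=1e-12)

    def test_time_translation_is_a_rigid_rotation(self, trypomastigote_like_params):
        s0 = effective_shape(trypomastigote_like_params, t=0.0)
        s1 = effective_shape(trypomastigote_like_params, t=0.37)
        # radii from the axis and z are preserved exactly
        assert np.allclose(
            np.hypot(s0.points[:, 0], s0.points[:, 1]),
            np.hypot(s1.points[:, 0], s1.points[:, 1]),
            atol=1e-12,
        )
        assert np.allclose(s0.points[:, 2], s1.points[:, 2], atol=1e-12)
        # and pairwise distances are preserved (rigid motion)
        d0 = np.linalg.norm(s0.points[:, None] - s0.points[None], axis=-1)
        d1 = np.linalg.norm(s1.points[:, None] - s1.points[None], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)


class TestSerialisation:
    def test_json_round_trip(self, trypomastigote_like_params, tmp_path):
        path = tmp_path / "params.json"
        trypomastigote_like_params.to_json(path)
        loaded = ShapeModelParams.from_json(path)
        for name in ("z", "A_r", "p_r", "A_b", "p_b", "p_o", "width"):
            assert np.allclose(getattr(loaded, name),
                               getattr(trypomastigote_like_params, name))
        assert loaded.omega_r == trypomastigote_like_params.omega_r
        assert loaded.f_b == trypomastigote_like_params.f_b
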