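"""Alignment, shape metric, event-triggered profiles, fits, contact force."""

import numpy as np
import pytest

from gaitflux.core import RegionPair, ShapeSeries, SpeedSeries, Track
from gaitflux.kinematics_features import (
    ContactForceParams,
    alignment,
    contact_force,
    event_triggered_average,
    fit_transition_profile,
    shape_metric,
    shape_series,
    speed_shape_trajectory,
)


def _oriented_track(motion_angle, body_angle, v=100.0, n=50, dt=0.01):
    t = dt * np.arange(n)
    d = np.array([np.cos(motion_angle), np.sin(motion_angle)])
    e = np.array([np.cos(body_angle), np.sin(body_angle)])
    return Track(times=t, positions=np.outer(v * t, d),
                 orientation=np.tile(e, (n, 1)))


class TestAlignment:
    @pytest.mark.parametrize(
        "motion,body,expected",
        [(0.3, 0.3, 1.0), (0.3, 0.3 + np.pi, -1.0), (0.3, 0.3 + np.pi / 2, 0.0)],
        ids=["parallel", "antiparallel", "perpendicular"],
    )
    def test_canonical_geometries(self, motion, body, expected):
        al = alignment(_oriented_track(motion, body))
        assert np.allclose(al.d[al.defined], expected, atol=1e-9)

    def test_slow_frames_are_undefined_not_interpolated(self):
        tr = _oriented_track(0.0, 0.0, v=0.1)
        al = alignment(tr, speed_floor=1.0)
        assert not al.defined.any()
        assert np.all(np.isnan(al.d))

    def test_invariant_under_global_rotation(self):
        base = alignment(_oriented_track(0.2, 1.0))
        rotated = alignment(_oriented_track(0.2 + 0.9, 1.0 + 0.9))
        assert np.allclose(base.d[base.defined], rotated.d[rotated.defined],
                           atol=1e-9)

    def test_missing_orientation_rejected(self):
        tr = Track(times=np.arange(5) * 0.1, positions=np.zeros((5, 2)))
        with pytest.raises(ValueError, match="orientation"):
            alignment(tr)


class TestShapeMetric:
    def test_three_four_five_triangle(self):
        body = np.zeros((10, 10), dtype=bool)
        full = np.zeros((10, 10), dtype=bool)
        body[0, 0] = True
        full[0, 0] = True
        full[4, 3] = True  # offset (3, 4) from the single body pixel
        assert shape_metric(RegionPair(body, full, 1.0)) == pytest.approx(5.0)

    def test_shared_centroid_gives_zero(self):
        body = np.zeros((21, 21), dtype=bool)
        body[8:13, 8:13] = True
        full = body.copy()
        full[6:15, 6:15] = True
        assert shape_metric(RegionPair(body, full, 1.0)) == pytest.approx(0.0)

    def test_analytic_lobe_offset_recovered_to_half_pixel(self):
        # symmetric body block; lobe block centered 7 pixels away
        body = np.zeros((41, 41), dtype=bool)
        body[18:23, 18:23] = True
        full = body.copy()
        full[18:23, 25:30] = True  # lobe centroid at col 27 vs body col 20
        lam = shape_metric(RegionPair(body, full, pixel_size=0.5))
        assert abs(lam - 7 * 0.5) <= 0.25

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        body = np.zeros((60, 60), dtype=bool)
        body[10:20, 10:18] = True
        full = body.copy()
        full[12:18, 20:28] = True
        lam0 = shape_metric(RegionPair(body, full, 1.0))
        shifted = RegionPair(np.roll(body, (7, 11), (0, 1)),
                             np.roll(full, (7, 11), (0, 1)), 1.0)
        assert shape_metric(shifted) == pytest.approx(lam0)

    def test_empty_flagellar_region_rejected(self):
        body = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            shape_metric(RegionPair(body, body.copy(), 1.0))


def _pulse_series(center, sigma=0.0086, peak=1284.0, baseline=428.0,
                  dt=5e-4, span=0.3, noise=0.0, rng=None):
    t = np.arange(0.0, span, dt)
    v = baseline + peak * np.exp(-((t - center) ** 2) / (2 * sigma**2))
    if noise and rng is not None:
        v = np.clip(v + rng.normal(0, noise, t.size), 0, None)
    return SpeedSeries(t, v)


class TestEventTriggeredAverage:
    def test_identical_traces_have_zero_sd(self):
        traces = [_pulse_series(0.15) for _ in range(4)]
        prof = event_triggered_average(traces, [(i, 0.15) for i in range(4)],
                                       window=0.1)
        assert np.nanmax(prof.sd) == pytest.approx(0.0, abs=1e-9)
        center = np.argmin(np.abs(prof.lags))
        assert prof.mean[center] == pytest.approx(428.0 + 1284.0, rel=1e-6)

    def test_constant_offset_traces_average_to_midline(self):
        t = np.arange(0.0, 1.0, 0.01)
        lo = SpeedSeries(t, np.full(t.size, 100.0))
        hi = SpeedSeries(t, np.full(t.size, 300.0))
        prof = event_triggered_average([lo, hi], [(0, 0.5), (1, 0.5)], window=0.5)
        assert np.allclose(prof.mean, 200.0)

    def test_partial_support_tracked_per_lag(self):
        t = np.arange(0.0, 0.2, 0.01)
        short = SpeedSeries(t, np.full(t.size, 50.0))
        long = SpeedSeries(np.arange(0.0, 1.0, 0.01), np.full(100, 50.0))
        prof = event_triggered_average([short, long], [(0, 0.19), (1, 0.5)],
                                       window=0.2)
        assert prof.n.min() == 1 and prof.n.max() == 2

    def test_too_few_events_rejected(self):
        tr = _pulse_series(0.1)
        with pytest.raises(ValueError, match="2 events"):
            event_triggered_average([tr], [(0, 0.1)], window=0.05)

    def test_noisy_shock_ensemble_recovers_pulse_width(self):
        # 50 pulses with sigma = 8.6 ms under seeded speed noise: the fitted
        # width of the averaged profile stays within 10%
        rng = np.random.default_rng(17)
        traces = [
            _pulse_series(0.15, noise=60.0, rng=rng) for _ in range(50)
        ]
        prof = event_triggered_average(traces, [(i, 0.15) for i in range(50)],
                                       window=0.12)
        fit = fit_transition_profile(prof, kind="gaussian_pulse")
        assert fit.converged
        assert abs(fit.sigma - 0.0086) / 0.0086 < 0.10


class TestProfileFits:
    @pytest.mark.parametrize("sigma", [0.0086, 0.0116])
    def test_noiseless_gaussian_recovery(self, sigma):
        sp = _pulse_series(0.15, sigma=sigma)
        fit = fit_transition_profile(sp.times, sp.v, kind="gaussian_pulse")
        assert fit.converged
        assert abs(fit.sigma - sigma) / sigma < 1e-6
        assert abs(fit.baseline - 428.0) < 1e-3

    def test_noiseless_tanh_recovery(self):
        t = np.linspace(-3.0, 3.0, 400)
        v = 5.0 + 0.5 * (428.0 - 5.0) * (1 - np.tanh(t / 0.640))
        fit = fit_transition_profile(t, v, kind="tanh_switch")
        assert fit.converged
        assert abs(fit.tau - 0.640) / 0.640 < 1e-6

    def test_noisy_tanh_ensemble_within_ten_percent(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            t = np.linspace(-3.0, 3.0, 200)
            v = 5.0 + 0.5 * (428.0 - 5.0) * (1 - np.tanh(t / 0.640))
            v = v + rng.normal(0, 20.0, t.size)
            fit = fit_transition_profile(t, v, kind="tanh_switch")
            hits += fit.converged and abs(fit.tau - 0.640) / 0.640 < 0.10
        assert hits >= 95

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            fit_transition_profile(np.arange(4.0), np.arange(4.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            fit_transition_profile(np.arange(10.0), np.arange(10.0), kind="spline")


class TestContactForce:
    def test_zero_deflection_means_zero_force(self):
        assert contact_force(ContactForceParams(L=12.0, delta=0.0)) == 0.0

    def test_reference_example(self):
        f = contact_force(ContactForceParams(EI=840.0, L=12.0, delta=2.0))
        assert f == pytest.approx(3 * 840 * 2 / 12**3)
        assert f == pytest.approx(2.917, abs=5e-4)

    def test_scaling_laws(self):
        base = ContactForceParams(EI=840.0, L=10.0, delta=1.0)
        assert contact_force(
            ContactForceParams(EI=840.0, L=10.0, delta=2.0)
        ) == pytest.approx(2 * contact_force(base))
        assert contact_force(
            ContactForceParams(EI=1680.0, L=10.0, delta=1.0)
        ) == pytest.approx(2 * contact_force(base))
        assert contact_force(
            ContactForceParams(EI=840.0, L=20.0, delta=1.0)
        ) == pytest.approx(contact_force(base) / 8)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ContactForceParams(L=0.0, delta=1.0)


class TestSpeedShapeTrajectory:
    def test_degenerate_point_has_zero_area(self):
        t = np.arange(0.0, 1.0, 0.01)
        path = speed_shape_trajectory(
            SpeedSeries(t, np.full(t.size, 100.0)),
            ShapeSeries(t, np.full(t.size, 3.0)),
        )
        assert path.signed_area == pytest.approx(0.0, abs=1e-9)

    def test_counterclockwise_circle_area(self):
        t = np.linspace(0.0, 1.0, 2001)
        v = 10.0 + np.cos(2 * np.pi * t)
        lam = 10.0 + np.sin(2 * np.pi * t)
        path = speed_shape_trajectory(SpeedSeries(t, v), ShapeSeries(t, lam))
        assert path.signed_area == pytest.approx(np.pi, abs=1e-4)

    def test_disjoint_supports_rejected(self):
        t = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(ValueError, match="disjoint"):
            speed_shape_trajectory(
                SpeedSeries(t, np.ones(t.size)),
                ShapeSeries(t + 10.0, np.ones(t.size)),
            )

    def test_excitation_precedes_shape_relaxation(self):
        """In a stop→shock→run event the speed pulse peaks before the shape
        metric reaches its plateau, producing a non-degenerate loop."""
        from gaitflux import presets
        from gaitflux.core import GaitStateSequence
        from gaitflux.kinematics_features import shape_series as mk_shape
        from gaitflux.synthetic_motility import (
            SimulationConfig,
            emit_speed_trace,
            synthesize_region_masks,
            synthesize_track2d,
        )

        cfg = SimulationConfig(frame_interval=2e-3, stop_speed_sd=1.0)
        seq = GaitStateSequence(
            boundaries=np.array([0.0, 0.4, 0.45, 1.0]),
            states=np.array([0, 2, 1]),
            censored_first=False,
            censored_last=False,
        )
        sp = emit_speed_trace(seq, cfg, seed=4)
        tr = synthesize_track2d(seq, sp, cfg, seed=4)
        pairs = synthesize_region_masks(tr, cfg, seed=4)
        lam = mk_shape(pairs, tr.times)
        path = speed_shape_trajectory(sp, lam)
        t_peak_v = path.times[int(np.argmax(path.v))]
        # time at which lambda first reaches 90% of its final plateau
        plateau = np.median(path.lam[path.times > 0.7])
        t_shape = path.times[int(np.argmax(path.lam >= 0.9 * plateau))]
        assert t_peak_v < t_shape
        assert abs(path.signed_area) > 0.0
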