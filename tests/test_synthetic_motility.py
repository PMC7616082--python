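"""Generator fidelity: sojourn statistics, emission shapes, track geometry."""

import numpy as np
import pytest

from gaitflux import presets
from gaitflux.core import GaitStateSequence
from gaitflux.ctmc_inference import (
    RateMatrix,
    sojourn_exponentiality_check,
    stationary_distribution,
)
from gaitflux.gait_segmentation import compute_speed, discretize_gaits
from gaitflux.kinematics_features import alignment, shape_metric
from gaitflux.synthetic_motility import (
    SimulationConfig,
    emit_speed_trace,
    simulate_cohort,
    simulate_gait_sequence,
    synthesize_region_masks,
    synthesize_track2d,
)


@pytest.fixture(scope="module")
def config():
    return SimulationConfig()


@pytest.fixture(scope="module")
def long_sequence(config):
    """One 1e5 s jump-process realization of the reference generator."""
    return simulate_gait_sequence(config, duration=1e5, seed=42)


class TestConfigValidation:
    def test_frame_interval_must_resolve_shocks(self):
        with pytest.raises(ValueError, match="resolve"):
            SimulationConfig(frame_interval=0.01)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            SimulationConfig(run_speed_mean=-1.0)

    def test_stop_jitter_may_be_zero(self):
        assert SimulationConfig(stop_speed_sd=0.0).stop_speed_sd == 0.0


class TestGillespie:
    def test_mean_stop_sojourn_matches_generator(self, long_sequence):
        mask = long_sequence.uncensored & (long_sequence.states == presets.STOP)
        mean_stop = long_sequence.sojourns[mask].mean()
        assert abs(mean_stop - 1 / 0.132) / (1 / 0.132) < 0.02

    def test_symmetric_two_state_occupancy(self):
        q = RateMatrix(np.array([[-1.0, 1.0], [1.0, -1.0]]))
        cfg = SimulationConfig(rate_matrix=q)
        seq = simulate_gait_sequence(cfg, duration=1e4, seed=3)
        occ = seq.occupancy(2)
        frac = occ / occ.sum()
        assert abs(frac[0] - 0.5) < 0.02

    def test_every_shock_exit_lands_in_run(self, long_sequence):
        s = long_sequence.states
        after_shock = s[1:][s[:-1] == presets.SHOCK]
        assert after_shock.size > 500
        assert np.all(after_shock == presets.RUN)

    def test_no_shock_to_stop_jump_ever(self, long_sequence):
        s = long_sequence.states
        assert not np.any((s[:-1] == presets.SHOCK) & (s[1:] == presets.STOP))

    def test_occupancy_converges_to_stationary(self, long_sequence, config):
        pi = stationary_distribution(config.rate_matrix).pi
        occ = long_sequence.occupancy(3)
        assert np.abs(occ / occ.sum() - pi).max() < 0.01

    def test_sojourns_pass_exponentiality_across_seeds(self, config):
        # nominal pass rate 99% at alpha = 0.01
        passed = total = 0
        for s in range(20):
            seq = simulate_gait_sequence(config, duration=2000.0, seed=s)
            for res in sojourn_exponentiality_check([seq], alpha=0.01,
                                                    n_boot=499, seed=s):
                if not res.skipped:
                    total += 1
                    passed += res.passed
        assert total >= 40
        assert passed / total >= 0.95

    def test_determinism_and_seed_sensitivity(self, config):
        a = simulate_gait_sequence(config, duration=50.0, seed=9)
        b = simulate_gait_sequence(config, duration=50.0, seed=9)
        c = simulate_gait_sequence(config, duration=50.0, seed=10)
        assert np.array_equal(a.boundaries, b.boundaries)
        assert np.array_equal(a.states, b.states)
        assert not (
            a.states.size == c.states.size
            and np.array_equal(a.boundaries, c.boundaries)
        )

    def test_absorbing_state_rejected(self):
        q = RateMatrix(np.array([[0.0, 0.0], [1.0, -1.0]]))
        with pytest.raises(ValueError, match="absorbing"):
            simulate_gait_sequence(SimulationConfig(rate_matrix=q), duration=10.0)

    def test_final_sojourn_censored_and_span_exact(self, config):
        seq = simulate_gait_sequence(config, duration=25.0, seed=1)
        assert seq.censored_last and not seq.censored_first
        assert seq.boundaries[-1] == 25.0


def _manual_sequence(states, sojourns):
    return GaitStateSequence(
        boundaries=np.concatenate(([0.0], np.cumsum(sojourns))),
        states=np.asarray(states),
        censored_first=False,
        censored_last=False,
    )


class TestSpeedEmission:
    def test_all_stop_with_zero_jitter_is_silent(self):
        cfg = SimulationConfig(stop_speed_sd=0.0)
        seq = _manual_sequence([0], [5.0])
        sp = emit_speed_trace(seq, cfg, seed=0)
        assert np.all(sp.v == 0.0)

    def test_shock_pulse_exceeds_cutoff(self, config):
        seq = _manual_sequence([1, 2, 1], [0.3, 0.05, 0.3])
        sp = emit_speed_trace(seq, config, seed=1)
        in_shock = seq.frame_labels(sp.times) == presets.SHOCK
        assert sp.v[in_shock].max() > 500.0
        assert np.all(sp.v[in_shock] >= 500.0)

    def test_shock_peak_means_satisfy_clt(self, config):
        # 100 independent shocks; sample mean of per-shock maxima should sit
        # within 2 standard errors of the 1712 um/s peak parameter
        states = np.tile([1, 2], 100)
        sojourns = np.tile([0.3, 0.05], 100)
        seq = _manual_sequence(states, sojourns)
        sp = emit_speed_trace(seq, config, seed=5)
        labels = seq.frame_labels(sp.times)
        maxima = []
        for m in range(1, 200, 2):
            sel = (sp.times >= seq.boundaries[m]) & (sp.times < seq.boundaries[m + 1])
            maxima.append(sp.v[sel].max())
        mean_peak = np.mean(maxima)
        assert abs(mean_peak - 1712.0) < 2 * 392.0 / np.sqrt(100)

    def test_run_band_respected(self, config):
        seq = _manual_sequence([1], [20.0])
        sp = emit_speed_trace(seq, config, seed=2)
        assert sp.v.min() >= presets.STOP_SPEED_MAX_UMS
        assert sp.v.max() < presets.RUN_SPEED_MAX_UMS

    def test_runstop_transition_crosses_cutoff_at_jump(self, config):
        seq = _manual_sequence([1, 0], [3.0, 5.0])
        sp = emit_speed_trace(seq, config, seed=3)
        labels = seq.frame_labels(sp.times)
        # run frames stay at/above the stop cutoff, stop frames below
        assert sp.v[labels == presets.RUN].min() >= presets.STOP_SPEED_MAX_UMS - 1.0
        assert np.all(sp.v[labels == presets.STOP] < presets.STOP_SPEED_MAX_UMS)

    def test_empty_sequence_rejected(self, config):
        with pytest.raises(ValueError):
            GaitStateSequence(boundaries=np.array([0.0]), states=np.array([], int))

    def test_deterministic_under_seed(self, config):
        seq = _manual_sequence([1, 2, 1, 0], [0.5, 0.04, 0.8, 2.0])
        a = emit_speed_trace(seq, config, seed=7)
        b = emit_speed_trace(seq, config, seed=7)
        assert np.array_equal(a.v, b.v)


class TestTrackSynthesis:
    def test_pure_run_without_rotation_is_straight(self):
        cfg = SimulationConfig(rotational_diffusion=0.0, run_speed_sd=1e-6)
        seq = _manual_sequence([1], [2.0])
        sp = emit_speed_trace(seq, cfg, seed=0)
        tr = synthesize_track2d(seq, sp, cfg, seed=0)
        disp = tr.positions[-1] - tr.positions[0]
        path_len = np.sum(sp.v[:-1]) * cfg.frame_interval
        assert np.linalg.norm(disp) == pytest.approx(path_len, rel=1e-9)
        # collinearity: cross products vanish
        d = np.diff(tr.positions, axis=0)
        cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
        assert np.abs(cross).max() < 1e-9

    def test_alignment_reverses_during_shock(self, config):
        seq = _manual_sequence([1, 2, 1], [0.5, 0.05, 0.5])
        sp = emit_speed_trace(seq, config, seed=11)
        tr = synthesize_track2d(seq, sp, config, seed=11)
        al = alignment(tr)
        labels = seq.frame_labels(tr.times)
        run_d = al.d[(labels == presets.RUN) & al.defined]
        shock_core = (labels == presets.SHOCK) & al.defined
        # drop the two boundary frames where central differences straddle
        # the reversal
        idx = np.flatnonzero(shock_core)[2:-2]
        assert np.nanmedian(run_d) > 0.99
        assert np.all(al.d[idx] < -0.99)

    def test_mismatched_grids_rejected(self, config):
        seq = _manual_sequence([1], [1.0])
        sp = emit_speed_trace(seq, config, seed=0)
        bad = type(sp)(sp.times + 5.0, sp.v)
        with pytest.raises(ValueError, match="grid"):
            synthesize_track2d(seq, bad, config, seed=0)

    def test_roundtrip_label_recovery(self, config):
        seq = simulate_gait_sequence(config, duration=100.0, seed=21)
        sp = emit_speed_trace(seq, config, seed=22)
        tr = synthesize_track2d(seq, sp, config, seed=23)
        est = discretize_gaits(compute_speed(tr))
        agreement = (est.frame_labels(tr.times) == tr.frame_states).mean()
        assert agreement >= 0.95


class TestRegionMasks:
    def test_isotropically_dilated_envelope_has_zero_lambda(self):
        from scipy import ndimage

        from gaitflux.core import RegionPair

        body = np.zeros((41, 41), dtype=bool)
        body[15:26, 15:26] = True
        full = ndimage.binary_dilation(body, iterations=3)
        lam = shape_metric(RegionPair(body=body, full=full, pixel_size=1.0))
        assert lam == pytest.approx(0.0, abs=1e-9)

    def test_state_dependent_lobe_flips_sign(self, config):
        seq = _manual_sequence([1, 2, 1], [0.5, 0.05, 0.5])
        sp = emit_speed_trace(seq, config, seed=31)
        tr = synthesize_track2d(seq, sp, config, seed=31)
        labels = tr.frame_states
        run_idx = int(np.flatnonzero(labels == presets.RUN)[10])
        shock_frames = np.flatnonzero(labels == presets.SHOCK)
        shock_idx = int(shock_frames[-1])  # late in the pulse: lobe in front
        pairs = synthesize_region_masks(
            tr, config, seed=0, frame_indices=[run_idx, shock_idx]
        )

        def offset_dot_e(pair, e):
            c_body = np.argwhere(pair.body).mean(axis=0)
            c_flag = np.argwhere(pair.flagellar).mean(axis=0)
            d = c_flag - c_body  # (row, col) = (y, x)
            return d[1] * e[0] + d[0] * e[1]

        run_proj = offset_dot_e(pairs[0], tr.orientation[run_idx])
        shock_proj = offset_dot_e(pairs[1], tr.orientation[shock_idx])
        assert run_proj < 0 < shock_proj

    def test_missing_orientation_rejected(self, config):
        from gaitflux.core import Track

        tr = Track(times=np.arange(3) * 1e-3, positions=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="orientation"):
            synthesize_region_masks(tr, config)


class TestCohort:
    def test_durations_within_range_and_reproducible(self, config):
        tracks = simulate_cohort(config, 5, seed=1, duration_range=(0.5, 8.0))
        again = simulate_cohort(config, 5, seed=1, duration_range=(0.5, 8.0))
        for a, b in zip(tracks, again):
            assert np.array_equal(a.positions, b.positions)
            assert 0.5 <= a.duration <= 8.0
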