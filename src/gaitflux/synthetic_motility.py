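"""Synthetic run-stop-shock motility generator.

Produces gait sequences, speed traces, 2D tracks and region-mask stacks
with the statistical structure the analysis pipeline assumes, so every
downstream stage can be exercised without microscopy recordings:

* Gait switching is an exact Gillespie simulation of the three-state CTMC
  (exponential sojourns at rates −q_ii, successors from the embedded chain),
  sampled onto a uniform frame grid fine enough to resolve shock pulses.
* Runs emit speeds fluctuating around 428 μm/s (mean-reverting
  Ornstein–Uhlenbeck noise with the startup-relaxation correlation time),
  kept inside the run band [40, 500) μm/s — consistent with the empirical
  speed histogram, in which essentially no run-band time lies above the
  shock cutoff.
* Shocks are Gaussian speed pulses peaking at draws from 1712 ± 392 μm/s.
  Each pulse's width is scaled to its sojourn so that the speed crosses the
  500 μm/s cutoff exactly at the jump times; this keeps the generator
  self-consistent with threshold segmentation (a fixed-width pulse would
  make the detected shock dwell systematically shorter than the simulated
  one).  The configured ``shock_width_sigma`` remains the stereotyped pulse
  scale and the frame-resolution bound.
* Run→stop conversions follow the switch-like tanh deceleration
  (τ = 640 ms), positioned so the speed crosses the stop cutoff at the jump
  time; stops emit only small positive jitter.
* Tracks integrate speed along a heading that diffuses rotationally during
  runs, reverses during shocks (body axis ê_R anti-aligned with motion,
  D = −1), randomizes on shock exit, and curls with a curvature ramp in the
  final deceleration window before stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import lfilter
from skimage.draw import ellipse as draw_ellipse

from . import presets
from .core import GaitStateSequence, RegionPair, SpeedSeries, Track
from .ctmc_inference import RateMatrix, stationary_distribution

__all__ = [
    "SimulationConfig",
    "simulate_gait_sequence",
    "emit_speed_trace",
    "synthesize_track2d",
    "synthesize_region_masks",
    "simulate_cohort",
]

STOP, RUN, SHOCK = presets.STOP, presets.RUN, presets.SHOCK


def _default_rate_matrix() -> RateMatrix:
    return presets.reference_rate_matrix()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic motility model (s, μm, μm/s, rad²/s).

    Defaults are the published run-stop-shock study conditions: the
    reference generator Q, run speeds 428 ± 64 μm/s, shock peaks
    1712 ± 392 μm/s with 8.6 ms stereotyped pulse width, 640 ms run→stop
    tanh relaxation, 50 ms startup relaxation, and the 40/500 μm/s gait
    bands.  The 0.5 ms frame interval comfortably resolves the shock
    pulses; rotational diffusion and the stop-approach curvature ramp are
    package choices (the reference data constrain neither directly).
    """

    rate_matrix: RateMatrix = field(default_factory=_default_rate_matrix)
    run_speed_mean: float = presets.RUN_SPEED_MEAN_UMS
    run_speed_sd: float = presets.RUN_SPEED_SD_UMS
    shock_peak_mean: float = presets.SHOCK_PEAK_MEAN_UMS
    shock_peak_sd: float = presets.SHOCK_PEAK_SD_UMS
    shock_width_sigma: float = presets.SHOCK_WIDTH_SIGMA_S
    stop_speed_sd: float = 5.0
    runstop_tau: float = presets.RUNSTOP_TAU_S
    startup_relaxation: float = presets.STARTUP_RELAXATION_S
    frame_interval: float = 5e-4
    duration: float = 10.0
    rotational_diffusion: float = 0.3
    stop_curvature_ramp: float = 3.0
    stop_max: float = presets.STOP_SPEED_MAX_UMS
    run_max: float = presets.RUN_SPEED_MAX_UMS
    body_length_um: float = presets.BODY_LENGTH_UM
    body_width_um: float = presets.BODY_WIDTH_UM
    flagella_offset_um: float = 5.0
    pixel_size_um: float = 0.5
    mask_shape: tuple[int, int] = (72, 72)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "run_speed_mean": self.run_speed_mean,
            "run_speed_sd": self.run_speed_sd,
            "shock_peak_mean": self.shock_peak_mean,
            "shock_peak_sd": self.shock_peak_sd,
            "shock_width_sigma": self.shock_width_sigma,
            "runstop_tau": self.runstop_tau,
            "startup_relaxation": self.startup_relaxation,
            "frame_interval": self.frame_interval,
            "duration": self.duration,
            "stop_max": self.stop_max,
            "run_max": self.run_max,
            "pixel_size_um": self.pixel_size_um,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.stop_speed_sd < 0:
            raise ValueError("stop_speed_sd must be non-negative")
        if self.rotational_diffusion < 0:
            raise ValueError("rotational_diffusion must be non-negative")
        if self.frame_interval >= self.shock_width_sigma:
            raise ValueError(
                "frame_interval must be smaller than shock_width_sigma "
                "to resolve shock pulses"
            )
        if not self.stop_max < self.run_max:
            raise ValueError("stop_max must be below run_max")


def simulate_gait_sequence(
    config: SimulationConfig,
    duration: float | None = None,
    seed: int | None = None,
    initial_state: int | None = None,
) -> GaitStateSequence:
    """Exact Gillespie simulation of the gait-switching jump process.

    Sojourn in state i is exponential with rate −q_ii; the successor is
    drawn from the embedded-chain row.  The path spans exactly ``duration``
    seconds: the last sojourn is truncated at the horizon and flagged as
    censored.  The initial state is drawn from the stationary distribution
    unless given.

    Raises
    ------
    ValueError
        For a non-conservative generator or one with an absorbing state.
    """
    Q = config.rate_matrix
    duration = config.duration if duration is None else float(duration)
    if duration <= 0:
        raise ValueError("duration must be positive")
    exits = Q.exit_rates
    if np.any(exits <= 0):
        raise ValueError(
            f"state(s) {list(Q.absorbing_states)} are absorbing (no outgoing "
            "rates); the gait process requires every state to be left"
        )
    k = Q.q / exits[:, None]
    np.fill_diagonal(k, 0.0)
    cum_k = np.cumsum(k, axis=1)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if initial_state is None:
        pi = stationary_distribution(Q).pi
        state = int(rng.choice(Q.n_states, p=pi))
    else:
        state = int(initial_state)
    boundaries = [0.0]
    states = []
    t = 0.0
    while True:
        t_next = t + rng.exponential(1.0 / exits[state])
        states.append(state)
        if t_next >= duration:
            boundaries.append(duration)
            break
        boundaries.append(t_next)
        t = t_next
        state = int(np.searchsorted(cum_k[state], rng.random(), side="right"))
        state = min(state, Q.n_states - 1)
    return GaitStateSequence(
        boundaries=np.asarray(boundaries),
        states=np.asarray(states, dtype=int),
        censored_first=False,
        censored_last=True,
    )


def _tanh_exit(config: SimulationConfig, a: float, b: float) -> tuple[float, float]:
    """Center and timescale of the run→stop tanh deceleration.

    Positioned so the profile crosses the stop cutoff exactly at the jump
    time ``b``; for runs shorter than the relaxation window the timescale
    is compressed so the run still starts near full speed.
    """
    x_c = math.atanh(1.0 - 2.0 * config.stop_max / config.run_speed_mean)
    tau_eff = min(config.runstop_tau, 0.45 * (b - a))
    return b - tau_eff * x_c, tau_eff


def emit_speed_trace(
    states: GaitStateSequence, config: SimulationConfig, seed: int | None = None
) -> SpeedSeries:
    """Sample the state-conditional speed process on the uniform frame grid."""
    if states.n_sojourns == 0:
        raise ValueError("empty state sequence")
    dt = config.frame_interval
    t0, t_end = states.boundaries[0], states.boundaries[-1]
    n = int(math.floor((t_end - t0) / dt - 1e-9)) + 1
    t = t0 + dt * np.arange(n)
    v = np.zeros(n)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # stationary OU noise for run-speed fluctuations, generated once
    a_ou = math.exp(-dt / config.startup_relaxation)
    innov = rng.normal(0.0, config.run_speed_sd * math.sqrt(1 - a_ou**2), n)
    if n > 0:
        innov[0] = rng.normal(0.0, config.run_speed_sd)
    ou = lfilter([1.0], [1.0, -a_ou], innov)

    bounds = states.boundaries
    seq = states.states
    for m in range(seq.size):
        a, b = bounds[m], bounds[m + 1]
        i0 = int(np.searchsorted(t, a - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, b - 1e-12, side="left"))
        if i1 <= i0:
            if seq[m] == SHOCK:  # keep the draw sequence deterministic
                rng.normal(config.shock_peak_mean, config.shock_peak_sd)
            continue
        seg_t = t[i0:i1]
        prev_state = seq[m - 1] if m > 0 else None
        next_state = seq[m + 1] if m + 1 < seq.size else None
        if seq[m] == RUN:
            decay = np.ones(seg_t.size)
            if next_state == STOP:
                t_c, tau_eff = _tanh_exit(config, a, b)
                decay = 0.5 * (1.0 - np.tanh((seg_t - t_c) / tau_eff))
            v_det = config.run_speed_mean * decay
            if prev_state == SHOCK:
                bump = 0.96 * config.run_max - config.run_speed_mean
                if bump > 0:
                    v_det = v_det + bump * np.exp(
                        -(seg_t - a) / config.startup_relaxation
                    )
            lower = 1.0
            if prev_state == STOP:
                v_det = v_det * (
                    1.0 - np.exp(-(seg_t - a + dt) / config.startup_relaxation)
                )
                lower = 0.0
            # noise envelope follows the squared profile so the tanh
            # threshold crossing is not blurred by fluctuations
            v[i0:i1] = np.clip(
                v_det + ou[i0:i1] * decay**2, lower, config.run_max - 2.0
            )
        elif seq[m] == STOP:
            v_det = np.zeros(seg_t.size)
            if prev_state == RUN:
                t_c, tau_eff = _tanh_exit(config, bounds[m - 1], a)
                v_det = (
                    config.run_speed_mean
                    * 0.5
                    * (1.0 - np.tanh((seg_t - t_c) / tau_eff))
                )
            elif prev_state == SHOCK:
                v_det = (
                    0.9
                    * config.stop_max
                    * np.exp(-(seg_t - a) / config.startup_relaxation)
                )
            jitter = (
                rng.normal(0.0, config.stop_speed_sd, seg_t.size)
                if config.stop_speed_sd > 0
                else 0.0
            )
            v[i0:i1] = np.clip(np.abs(v_det + jitter), 0.0, config.stop_max - 0.5)
        else:  # SHOCK
            peak = max(
                rng.normal(config.shock_peak_mean, config.shock_peak_sd),
                1.2 * config.run_max,
            )
            edge = 1.002 * config.run_max  # pulse value at the jump times
            sigma = (b - a) / (2.0 * math.sqrt(2.0 * math.log(peak / edge)))
            center = 0.5 * (a + b)
            v[i0:i1] = peak * np.exp(-((seg_t - center) ** 2) / (2.0 * sigma**2))
    return SpeedSeries(t, v)


def synthesize_track2d(
    states: GaitStateSequence,
    speeds: SpeedSeries,
    config: SimulationConfig,
    seed: int | None = None,
) -> Track:
    """Integrate a 2D trajectory from speeds, headings and gait states.

    Heading diffuses rotationally during runs (diffusivity
    ``rotational_diffusion`` rad²/s) and acquires a curvature ramp over the
    deceleration window before stops; during shocks the direction of motion
    is the reverse of the body axis (D = −1) and the heading randomizes on
    exit; during stops displacement directions are isotropic frame to
    frame, so the centroid jiggles without net drift.
    """
    t = speeds.times
    if t[0] < states.boundaries[0] - 1e-9 or t[-1] >= states.boundaries[-1] + 1e-9:
        raise ValueError("speed grid does not lie within the state sequence span")
    dt = speeds.dt
    n = t.size
    labels = states.frame_labels(t)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ux = np.empty(n)
    uy = np.empty(n)
    ex = np.empty(n)
    ey = np.empty(n)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    bounds = states.boundaries
    seq = states.states
    for m in range(seq.size):
        a, b = bounds[m], bounds[m + 1]
        i0 = int(np.searchsorted(t, a - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, b - 1e-12, side="left"))
        if i1 <= i0:
            continue
        seg_t = t[i0:i1]
        if seq[m] == RUN:
            dtheta = rng.normal(
                0.0,
                math.sqrt(2.0 * config.rotational_diffusion * dt),
                seg_t.size,
            )
            if (m + 1 < seq.size and seq[m + 1] == STOP
                    and config.stop_curvature_ramp > 0):
                window = min(config.runstop_tau, b - a)
                ramp = np.clip((seg_t - (b - window)) / window, 0.0, None)
                dtheta = dtheta + rng.choice((-1.0, 1.0)) * (
                    config.stop_curvature_ramp * ramp * dt
                )
            angles = theta + np.cumsum(dtheta)
            theta = float(angles[-1])
            ux[i0:i1] = np.cos(angles)
            uy[i0:i1] = np.sin(angles)
            ex[i0:i1] = ux[i0:i1]
            ey[i0:i1] = uy[i0:i1]
        elif seq[m] == SHOCK:
            # motion reverses while the body axis holds: pusher geometry
            ux[i0:i1] = -math.cos(theta)
            uy[i0:i1] = -math.sin(theta)
            ex[i0:i1] = math.cos(theta)
            ey[i0:i1] = math.sin(theta)
            theta = rng.uniform(0.0, 2.0 * math.pi)  # randomize on exit
        else:  # STOP: isotropic residual jiggle, frozen body axis
            angles = rng.uniform(0.0, 2.0 * math.pi, seg_t.size)
            ux[i0:i1] = np.cos(angles)
            uy[i0:i1] = np.sin(angles)
            ex[i0:i1] = math.cos(theta)
            ey[i0:i1] = math.sin(theta)
    disp = (speeds.v * dt)[:, None] * np.stack((ux, uy), axis=1)
    positions = np.concatenate(
        (np.zeros((1, 2)), np.cumsum(disp[:-1], axis=0)), axis=0
    )
    return Track(
        times=t.copy(),
        positions=positions,
        orientation=np.stack((ex, ey), axis=1),
        frame_states=labels,
    )


def synthesize_region_masks(
    track: Track,
    config: SimulationConfig,
    seed: int | None = None,
    frame_indices: np.ndarray | None = None,
) -> list[RegionPair]:
    """Per-frame body (𝒜) and body+flagella (ℬ) masks for the shape metric.

    The body is a filled ellipse (published mean dimensions 17.05 × 9.05 μm)
    oriented along ê_R; ℬ adds a one-pixel envelope plus a flagellar lobe
    whose centroid sits behind the body during runs, sweeps to the front
    during shocks (ramping over the shock so shape change lags the speed
    pulse), and hugs the body during stops.
    """
    if track.orientation is None:
        raise ValueError("region masks require per-frame orientation")
    if track.frame_states is None:
        raise ValueError(
            "region masks require per-frame gait labels (synthetic tracks "
            "carry them as frame_states)"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if frame_indices is None:
        frame_indices = np.arange(track.n_frames)
    frame_indices = np.asarray(frame_indices, dtype=int)
    px = config.pixel_size_um
    h, w = config.mask_shape
    c_row, c_col = h / 2.0, w / 2.0
    body_r = config.body_width_um / 2.0 / px
    body_c = config.body_length_um / 2.0 / px
    lobe_r = 3.0 / px
    lobe_c = 4.0 / px

    # per-frame shock progress (0→1 across each shock segment) so the lobe
    # sweeps forward over the pulse instead of jumping
    labels = track.frame_states
    progress = np.zeros(track.n_frames)
    change = np.flatnonzero(np.diff(labels)) + 1
    seg_edges = np.concatenate(([0], change, [labels.size]))
    for s0, s1 in zip(seg_edges[:-1], seg_edges[1:]):
        if labels[s0] == SHOCK:
            progress[s0:s1] = (np.arange(s1 - s0) + 1.0) / (s1 - s0)

    pairs: list[RegionPair] = []
    for i in frame_indices:
        e = track.orientation[i]
        angle = math.atan2(e[1], e[0])
        state = labels[i]
        if state == RUN:
            offset_um = -config.flagella_offset_um
        elif state == SHOCK:
            offset_um = config.flagella_offset_um * (0.2 + 0.8 * progress[i])
        else:
            offset_um = -0.5
        jitter = rng.normal(0.0, 0.1, 2)
        lobe_row = c_row + (offset_um / px) * math.sin(angle) + jitter[0]
        lobe_col = c_col + (offset_um / px) * math.cos(angle) + jitter[1]
        body = np.zeros((h, w), dtype=bool)
        rr, cc = draw_ellipse(
            c_row, c_col, body_r, body_c, shape=(h, w), rotation=angle
        )
        body[rr, cc] = True
        full = ndimage.binary_dilation(body, iterations=1)
        rr, cc = draw_ellipse(
            lobe_row, lobe_col, lobe_r, lobe_c, shape=(h, w), rotation=angle
        )
        full[rr, cc] = True
        pairs.append(RegionPair(body=body, full=full, pixel_size=px))
    return pairs


def simulate_cohort(
    config: SimulationConfig,
    n_tracks: int,
    seed: int | None = None,
    duration_range: tuple[float, float] = (0.5, 80.0),
) -> list[Track]:
    """Simulate a cohort of tracks with log-uniform durations.

    Track durations are drawn log-uniformly on ``duration_range``
    (default 0.5–80 s, the span of the reference recordings); each track
    gets independent child seeds for the jump process, the speed emission
    and the trajectory integration, so cohorts are reproducible from a
    single seed.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be at least 1")
    lo, hi = duration_range
    if not 0 < lo < hi:
        raise ValueError("duration_range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    durations = np.exp(rng.uniform(math.log(lo), math.log(hi), n_tracks))
    child = rng.integers(0, 2**31 - 1, size=(n_tracks, 3))
    tracks = []
    for i in range(n_tracks):
        states = simulate_gait_sequence(config, durations[i], seed=int(child[i, 0]))
        speeds = emit_speed_trace(states, config, seed=int(child[i, 1]))
        track = synthesize_track2d(states, speeds, config, seed=int(child[i, 2]))
        track.track_id = f"track_{i:04d}"
        tracks.append(track)
    return tracks
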