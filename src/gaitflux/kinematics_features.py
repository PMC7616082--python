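"""Kinematic and morphological observables of gait switching.

* **Alignment** ``D = v̂ · ê_R`` distinguishes puller-like runs (D = +1,
  flagella trailing) from pusher-like shocks (D = −1, flagella leading);
  it is undefined below a small speed floor where v̂ is ill-conditioned.
* **Shape metric** λ = ‖centroid(ℬ\\𝒜) − centroid(𝒜)‖: the separation
  between the flagellar and cell-body centers of mass, in μm.
* **Event-triggered averaging** superimposes speed traces around
  transition times and reports the per-lag mean ± sd profile.
* **Transition-profile fits**: shock-bracketed transitions are sharply
  peaked Gaussians (σ ≈ 8.6–11.6 ms), run→stop conversions are switch-like
  tanh relaxations (τ ≈ 640 ms); both are fit by nonlinear least squares
  with analytic moment/half-crossing initialization.
* **Contact force** ``F = 3EIδ/L³``: the cantilever-bending estimate of
  the force on a flagellum of rigidity EI and length L deflected by δ at
  the tip (shock-triggering threshold estimation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from . import presets
from .core import RegionPair, ShapeSeries, SpeedSeries, Track

__all__ = [
    "AlignmentSeries",
    "EventTriggeredProfile",
    "TransitionProfileFit",
    "ContactForceParams",
    "SpeedShapePath",
    "alignment",
    "shape_metric",
    "shape_series",
    "event_triggered_average",
    "fit_transition_profile",
    "contact_force",
    "speed_shape_trajectory",
]


@dataclass
class AlignmentSeries:
    """Instantaneous alignment D(t) ∈ [−1, 1]; NaN where undefined."""

    times: np.ndarray
    d: np.ndarray
    defined: np.ndarray


def alignment(track: Track, speed_floor: float = 1.0) -> AlignmentSeries:
    """D = v̂ · ê_R per frame.

    Frames whose speed falls below ``speed_floor`` (μm/s) yield an
    undefined alignment — the swimming direction is ill-defined at rest —
    flagged in ``defined`` and set to NaN, never interpolated.
    """
    if track.orientation is None:
        raise ValueError("alignment requires per-frame orientation")
    if track.n_frames < 2:
        raise ValueError("alignment requires at least 2 frames")
    vel = np.gradient(track.positions, track.times, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    defined = speed >= speed_floor
    d = np.full(track.n_frames, np.nan)
    d[defined] = np.einsum(
        "ij,ij->i", vel[defined] / speed[defined, None], track.orientation[defined]
    )
    return AlignmentSeries(times=track.times.copy(), d=d, defined=defined)


def shape_metric(pair: RegionPair) -> float:
    """λ (μm): distance between the flagellar and body centroids."""
    flag = pair.flagellar
    if not flag.any():
        raise ValueError("flagellar region ℬ\\𝒜 is empty; λ undefined")
    c_flag = np.argwhere(flag).mean(axis=0)
    c_body = np.argwhere(pair.body).mean(axis=0)
    return float(np.linalg.norm(c_flag - c_body) * pair.pixel_size)


def shape_series(pairs: Sequence[RegionPair], times: np.ndarray) -> ShapeSeries:
    """λ(t) over a mask stack."""
    times = np.asarray(times, dtype=float)
    if len(pairs) != times.size:
        raise ValueError("one mask pair per time point required")
    return ShapeSeries(times, np.array([shape_metric(p) for p in pairs]))


@dataclass
class EventTriggeredProfile:
    """Mean ± sd speed profile around aligned events, on a lag grid."""

    lags: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray


def event_triggered_average(
    speeds: Sequence[SpeedSeries],
    events: Sequence[tuple[int, float]],
    window: float,
    grid_dt: float | None = None,
) -> EventTriggeredProfile:
    """Superimpose and average speed traces around transition times.

    Parameters
    ----------
    speeds
        The contributing speed series.
    events
        ``(series_index, event_time)`` pairs; each trace is resampled by
        linear interpolation onto a common lag grid centered on its event.
    window
        Total window width in seconds (lags span ±window/2).
    grid_dt
        Lag-grid spacing; defaults to the median frame interval of the
        first contributing series.

    Shorter traces contribute partial support; the per-lag contributor
    count ``n`` tracks this.
    """
    events = list(events)
    if len(events) < 2:
        raise ValueError("event-triggered averaging needs at least 2 events")
    if grid_dt is None:
        grid_dt = speeds[events[0][0]].dt
    half = window / 2.0
    lags = np.arange(-half, half + grid_dt / 2.0, grid_dt)
    total = np.zeros(lags.size)
    total_sq = np.zeros(lags.size)
    count = np.zeros(lags.size, dtype=int)
    for idx, t_event in events:
        series = speeds[idx]
        t_abs = t_event + lags
        ok = (t_abs >= series.times[0]) & (t_abs <= series.times[-1])
        if not ok.any():
            continue
        vals = np.interp(t_abs[ok], series.times, series.v)
        total[ok] += vals
        total_sq[ok] += vals**2
        count[ok] += 1
    if not count.any():
        raise ValueError("no event window overlaps its trace")
    mean = np.full(lags.size, np.nan)
    sd = np.full(lags.size, np.nan)
    has = count > 0
    mean[has] = total[has] / count[has]
    var = np.zeros(lags.size)
    var[has] = np.maximum(total_sq[has] / count[has] - mean[has] ** 2, 0.0)
    sd[has] = np.sqrt(var[has])
    return EventTriggeredProfile(lags=lags, mean=mean, sd=sd, n=count)


@dataclass
class TransitionProfileFit:
    """Converged parameters of a Gaussian-pulse or tanh-switch speed fit."""

    kind: str
    amplitude: float
    center: float
    width: float  # sigma (gaussian_pulse) or tau (tanh_switch), seconds
    baseline: float
    residual_rms: float
    converged: bool
    covariance: np.ndarray | None = None

    @property
    def sigma(self) -> float:
        if self.kind != "gaussian_pulse":
            raise AttributeError("sigma only defined for gaussian_pulse fits")
        return self.width

    @property
    def tau(self) -> float:
        if self.kind != "tanh_switch":
            raise AttributeError("tau only defined for tanh_switch fits")
        return self.width


def _gaussian(t, baseline, amplitude, center, sigma):
    return baseline + amplitude * np.exp(-((t - center) ** 2) / (2.0 * sigma**2))


def _tanh_switch(t, v_stop, v_run, center, tau):
    return v_stop + 0.5 * (v_run - v_stop) * (1.0 - np.tanh((t - center) / tau))


def fit_transition_profile(
    times: np.ndarray | EventTriggeredProfile,
    values: np.ndarray | None = None,
    kind: str = "gaussian_pulse",
) -> TransitionProfileFit:
    """Nonlinear least-squares fit of a transition speed profile.

    ``gaussian_pulse``: v(t) = baseline + A·exp(−(t−c)²/2σ²) — the
    millisecond shock pulses.  ``tanh_switch``:
    v(t) = v_stop + ½(v_run − v_stop)(1 − tanh((t−c)/τ)) — the slower
    run→stop deceleration.  Initialization is analytic (moments /
    half-crossing), so the fits are seed-free.  Non-convergence is
    reported via ``converged=False``, never clamped.
    """
    if isinstance(times, EventTriggeredProfile):
        prof = times
        ok = prof.n > 0
        t = prof.lags[ok]
        y = prof.mean[ok]
    else:
        t = np.asarray(times, dtype=float)
        y = np.asarray(values, dtype=float)
    if kind not in ("gaussian_pulse", "tanh_switch"):
        raise ValueError(f"unknown profile kind {kind!r}")
    if t.size < 5:
        raise ValueError("profile fitting needs at least 5 points")
    span = t[-1] - t[0]
    if kind == "gaussian_pulse":
        edge = max(1, t.size // 10)
        baseline0 = float(np.median(np.concatenate((y[:edge], y[-edge:]))))
        peak_idx = int(np.argmax(y))
        amp0 = max(float(y[peak_idx] - baseline0), 1e-9)
        center0 = float(t[peak_idx])
        above = y - baseline0 > amp0 / 2.0
        sigma0 = max(
            float(above.sum()) * (span / t.size) / 2.355, span / t.size
        )
        p0 = (baseline0, amp0, center0, sigma0)
        bounds = ([-np.inf, 0.0, t[0] - span, 1e-12],
                  [np.inf, np.inf, t[-1] + span, np.inf])
        model = _gaussian
    else:
        edge = max(1, t.size // 10)
        v_run0 = float(np.mean(y[:edge]))
        v_stop0 = float(np.mean(y[-edge:]))
        mid = 0.5 * (v_run0 + v_stop0)
        center0 = float(t[int(np.argmin(np.abs(y - mid)))])
        grad = np.gradient(y, t)
        slope = float(grad[int(np.argmin(np.abs(t - center0)))])
        tau0 = abs((v_run0 - v_stop0) / (2.0 * slope)) if slope != 0 else span / 10.0
        tau0 = min(max(tau0, span / t.size), span)
        p0 = (v_stop0, v_run0, center0, tau0)
        bounds = ([-np.inf, -np.inf, t[0] - span, 1e-12],
                  [np.inf, np.inf, t[-1] + span, np.inf])
        model = _tanh_switch
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, pcov, converged = np.asarray(p0), None, False
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if kind == "gaussian_pulse":
        baseline, amplitude, center, width = popt
    else:
        baseline, v_run, center, width = popt
        amplitude = v_run - baseline
    return TransitionProfileFit(
        kind=kind,
        amplitude=float(amplitude),
        center=float(center),
        width=float(abs(width)),
        baseline=float(baseline),
        residual_rms=rms,
        converged=bool(converged),
        covariance=pcov,
    )


@dataclass(frozen=True)
class ContactForceParams:
    """Cantilever parameters: EI (pN·μm²), L (μm), tip deflection δ (μm)."""

    EI: float = presets.FLAGELLAR_EI_PN_UM2
    L: float = 12.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.EI <= 0 or self.L <= 0:
            raise ValueError("EI and L must be strictly positive")
        if self.delta < 0:
            raise ValueError("tip deflection must be non-negative")


def contact_force(params: ContactForceParams) -> float:
    """Threshold contact force F = 3EIδ/L³ in pN."""
    return 3.0 * params.EI * params.delta / params.L**3


@dataclass
class SpeedShapePath:
    """Time-ordered (v, λ) trajectory with its loop-area diagnostic.

    The signed enclosed area of the closed (v, λ) path is an added
    convenience diagnostic of loop asymmetry, not a reference observable.
    """

    times: np.ndarray
    v: np.ndarray
    lam: np.ndarray
    signed_area: float


def speed_shape_trajectory(
    speeds: SpeedSeries, shapes: ShapeSeries
) -> SpeedShapePath:
    """Pair speed and shape into a (v, λ) path on their common time support.

    Grids are merged by linear interpolation; the signed enclosed area of
    the closed path (shoelace formula, last point joined to first) is
    reported as a loop-asymmetry diagnostic.
    """
    t0 = max(speeds.times[0], shapes.times[0])
    t1 = min(speeds.times[-1], shapes.times[-1])
    if t1 <= t0:
        raise ValueError("speed and shape series have disjoint time supports")
    dts = [d for d in (speeds.dt, np.median(np.diff(shapes.times))
                       if shapes.times.size > 1 else 0.0) if d > 0]
    dt = min(dts) if dts else (t1 - t0)
    n = max(int(round((t1 - t0) / dt)) + 1, 2)
    t = np.linspace(t0, t1, n)
    v = np.interp(t, speeds.times, speeds.v)
    lam = np.interp(t, shapes.times, shapes.lam)
    area = 0.5 * float(
        np.sum(v * np.roll(lam, -1) - np.roll(v, -1) * lam)
    )
    return SpeedShapePath(times=t, v=v, lam=lam, signed_area=area)
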