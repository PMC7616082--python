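"""Speed-based three-state gait discretization.

Tracks are converted to instantaneous speed and thresholded into the three
gaits using the published cutoffs — stop ``[0, 40)``, run ``[40, 500)``,
shock ``[500, ∞) μm/s`` — resolved as half-open bands with boundary values
assigned upward (the published band edges overlap at exactly 40 and 500;
the half-open convention is deterministic and differs only on a measure-zero
set).  Short label chatter is debounced by merging sub-``min_dwell`` runs of
identical labels into the preceding state, except genuine shocks bracketed
by two *different* states (e.g. stop→shock→run), which are kept however
brief.  First and last sojourns of every sequence are censored: recording
starts and ends mid-sojourn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GaitStateSequence, SpeedSeries, Track, TransitionCounts
from . import presets

__all__ = [
    "GaitThresholds",
    "compute_speed",
    "discretize_gaits",
    "dwell_fractions",
    "extract_transitions",
]


@dataclass(frozen=True)
class GaitThresholds:
    """Speed cutoffs (μm/s) separating stop/run and run/shock."""

    stop_max: float = presets.STOP_SPEED_MAX_UMS
    run_max: float = presets.RUN_SPEED_MAX_UMS

    def __post_init__(self) -> None:
        if not 0 < self.stop_max < self.run_max:
            raise ValueError("thresholds must satisfy 0 < stop_max < run_max")

    def labels(self, v: np.ndarray) -> np.ndarray:
        """Frame-wise gait label for speeds ``v`` (half-open bands)."""
        v = np.asarray(v)
        if np.any(v < 0):
            raise ValueError("speeds must be non-negative")
        return np.digitize(v, [self.stop_max, self.run_max]).astype(int)


def compute_speed(track: Track, smoothing_window: int = 1) -> SpeedSeries:
    """Instantaneous speed from central-difference displacement rates.

    Endpoints use one-sided differences.  ``smoothing_window`` applies a
    centered moving average of odd width (1 = no smoothing).

    Raises
    ------
    ValueError
        For tracks with fewer than 3 frames or strongly non-uniform sampling
        (max/min frame interval ratio ≥ 1.5).
    """
    if track.n_frames < 3:
        raise ValueError("speed estimation needs at least 3 frames")
    dts = np.diff(track.times)
    if dts.max() / dts.min() >= 1.5:
        raise ValueError("sampling must be near-uniform (interval ratio < 1.5)")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")
    vel = np.gradient(track.positions, track.times, axis=0)
    v = np.linalg.norm(vel, axis=1)
    if smoothing_window > 1:
        kernel = np.full(smoothing_window, 1.0 / smoothing_window)
        # reflect-pad so endpoints average over real samples only
        half = smoothing_window // 2
        padded = np.pad(v, half, mode="edge")
        v = np.convolve(padded, kernel, mode="valid")
    return SpeedSeries(track.times.copy(), v)


def _merge_short_segments(
    seg_states: list[int], seg_len: list[int], min_frames: int
) -> tuple[list[int], list[int]]:
    """Debounce: absorb short interior segments into the preceding state.

    Shock segments flanked by two distinct states are exempt (a genuine
    stop→shock→run event can be arbitrarily brief).  Boundary segments are
    left alone — they are censored downstream anyway.
    """
    changed = True
    while changed:
        changed = False
        i = 1
        while i < len(seg_states) - 1:
            if seg_len[i] < min_frames:
                exempt = (
                    seg_states[i] == presets.SHOCK
                    and seg_states[i - 1] != seg_states[i + 1]
                )
                if not exempt:
                    seg_len[i - 1] += seg_len[i]
                    del seg_states[i], seg_len[i]
                    if seg_states[i - 1] == seg_states[i]:  # coalesce flanks
                        seg_len[i - 1] += seg_len[i]
                        del seg_states[i], seg_len[i]
                    changed = True
                    continue
            i += 1
    return seg_states, seg_len


def discretize_gaits(
    speeds: SpeedSeries,
    thresholds: GaitThresholds | None = None,
    min_dwell: float | None = None,
    sequence_id: str = "",
) -> GaitStateSequence:
    """Collapse a speed trace into a jump-time gait representation.

    Parameters
    ----------
    speeds
        Uniformly sampled speed series.
    thresholds
        Speed cutoffs; defaults to the published 40/500 μm/s bands.
    min_dwell
        Minimum dwell in seconds below which interior label runs are merged
        into the preceding state.  Defaults to two frame intervals, a light
        debounce against single-frame threshold chatter.
    """
    thresholds = thresholds or GaitThresholds()
    labels = thresholds.labels(speeds.v)
    dt = speeds.dt if speeds.times.size > 1 else 0.0
    if min_dwell is None:
        min_dwell = 2.0 * dt
    # run-length encode the frame labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [labels.size])))
    seg_states = [int(labels[s]) for s in starts]
    seg_len = [int(l) for l in lengths]
    if dt > 0 and min_dwell > 0:
        min_frames = max(1, math.ceil(min_dwell / dt - 1e-9))
        seg_states, seg_len = _merge_short_segments(seg_states, seg_len, min_frames)
    # each frame covers [t, t + dt); boundaries at segment-start frame times
    edges = np.concatenate(([0], np.cumsum(seg_len)))
    boundaries = np.empty(len(seg_states) + 1)
    boundaries[:-1] = speeds.times[edges[:-1]]
    boundaries[-1] = speeds.times[-1] + (dt if dt > 0 else 1.0)
    return GaitStateSequence(
        boundaries=boundaries,
        states=np.asarray(seg_states, dtype=int),
        censored_first=True,
        censored_last=True,
        sequence_id=sequence_id,
    )


def dwell_fractions(
    sequences: Iterable[GaitStateSequence], n_states: int = 3
) -> np.ndarray:
    """Fraction of total time spent in each state (censored time included).

    Censored sojourns carry real occupancy, so they count here even though
    they are excluded from rate estimation.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no state sequences provided")
    occ = np.zeros(n_states)
    for seq in sequences:
        occ += seq.occupancy(n_states, censored=True)
    total = occ.sum()
    if total <= 0:
        raise ValueError("total duration must be positive")
    return occ / total


def extract_transitions(
    sequences: Iterable[GaitStateSequence], n_states: int = 3
) -> TransitionCounts:
    """Pooled pairwise jump counts and rate-estimation exposure.

    Every observed jump is counted and every observed second of occupancy is
    exposure — the standard CTMC MLE treatment of boundary truncation.  By
    memorylessness, the observed tail of a left-censored first sojourn is
    exponential with the unchanged rate, so its exposure and exit are valid
    data; a right-censored last sojourn contributes exposure without an
    event.  Dropping censored exposure instead (a completed-sojourns-only
    estimator) is length-biased against long sojourns whenever dwell times
    are comparable to track durations, which is exactly the stop-state
    regime here.  Censored sojourns are excluded from sojourn-*duration*
    statistics (see :meth:`GaitStateSequence.uncensored`), not from here.
    """
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    occ = np.zeros(n_states)
    n_seq = 0
    for seq in sequences:
        n_seq += 1
        occ += seq.occupancy(n_states, censored=True)
        if seq.n_sojourns >= 2:
            np.add.at(counts, (seq.states[:-1], seq.states[1:]), 1)
    if n_seq == 0:
        raise ValueError("no state sequences provided")
    return TransitionCounts(counts=counts, occupancy=occ, n_sequences=n_seq)
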