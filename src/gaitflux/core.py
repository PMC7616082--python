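"""Core data containers shared across the pipeline.

Everything downstream operates on a handful of small, validated types:
a 2D :class:`Track` (the raw observable), a :class:`SpeedSeries`, the
piecewise-constant :class:`GaitStateSequence`, pooled
:class:`TransitionCounts`, and the pixel-region pair used by the shape
metric.  Containers are thin ``dataclass`` wrappers over NumPy arrays with
eager invariant checks; they carry units in their docstrings (seconds and
micrometers throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Track",
    "SpeedSeries",
    "GaitStateSequence",
    "TransitionCounts",
    "RegionPair",
    "ShapeSeries",
]

_ORIENT_NORM_TOL = 1e-6


@dataclass
class Track:
    """A time-stamped 2D swimming trajectory.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, near-uniform.
    positions
        ``(n, 2)`` array of x, y positions in micrometers.
    orientation
        Optional ``(n, 2)`` array of unit body-axis vectors (ê_R).
    track_id
        Identifier used in reports and file names.
    frame_states
        Optional per-frame ground-truth gait labels (synthetic tracks only).
    """

    times: np.ndarray
    positions: np.ndarray
    orientation: np.ndarray | None = None
    track_id: str = ""
    frame_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.positions.shape != (self.times.size, 2):
            raise ValueError("positions must have shape (n_frames, 2)")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != self.positions.shape:
                raise ValueError("orientation must have shape (n_frames, 2)")
            norms = np.linalg.norm(self.orientation, axis=1)
            if np.any(np.abs(norms - 1.0) > _ORIENT_NORM_TOL):
                raise ValueError("orientation vectors must have unit norm")
        if self.frame_states is not None:
            self.frame_states = np.asarray(self.frame_states, dtype=int)
            if self.frame_states.shape != self.times.shape:
                raise ValueError("frame_states must match times")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Track span in seconds (0 for tracks with < 2 frames)."""
        return float(self.times[-1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class SpeedSeries:
    """Instantaneous speed ``v(t)`` (um/s) on a uniform time grid."""

    times: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.times.shape != self.v.shape or self.times.ndim != 1:
            raise ValueError("times and v must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("empty speed series")
        if np.any(self.v < 0):
            raise ValueError("speeds must be non-negative")

    @property
    def dt(self) -> float:
        """Median frame interval in seconds."""
        return float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.0


@dataclass
class GaitStateSequence:
    """Piecewise-constant gait path X(t) in jump representation.

    The process occupies ``states[i]`` on ``[boundaries[i], boundaries[i+1])``;
    interior boundaries are the jump times ``{T_n}``.  The first and last
    sojourns may be censored (recording started or ended mid-sojourn, or the
    simulation truncated the final sojourn); censored sojourns are excluded
    from sojourn-time statistics and transition counts but retain their
    occupancy for dwell-fraction purposes.
    """

    boundaries: np.ndarray
    states: np.ndarray
    censored_first: bool = True
    censored_last: bool = True
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.boundaries.ndim != 1 or self.states.ndim != 1:
            raise ValueError("boundaries and states must be 1-D")
        if self.boundaries.size != self.states.size + 1:
            raise ValueError("need exactly one more boundary than states")
        if self.states.size == 0:
            raise ValueError("empty state sequence")
        if not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("sojourns must all be positive")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("consecutive states must differ (no self-transitions)")

    @property
    def n_sojourns(self) -> int:
        return self.states.size

    @property
    def jump_times(self) -> np.ndarray:
        """Interior jump times ``{T_n}`` in seconds."""
        return self.boundaries[1:-1]

    @property
    def sojourns(self) -> np.ndarray:
        """Sojourn durations in seconds (censored ones included)."""
        return np.diff(self.boundaries)

    @property
    def duration(self) -> float:
        return float(self.boundaries[-1] - self.boundaries[0])

    @property
    def uncensored(self) -> np.ndarray:
        """Boolean mask over sojourns: True where fully observed."""
        mask = np.ones(self.states.size, dtype=bool)
        if self.censored_first:
            mask[0] = False
        if self.censored_last:
            mask[-1] = False
        return mask

    def frame_labels(self, times: np.ndarray) -> np.ndarray:
        """State occupied at each query time (right-open sojourn intervals)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.boundaries, times, side="right") - 1
        idx = np.clip(idx, 0, self.states.size - 1)
        return self.states[idx]

    def occupancy(self, n_states: int, censored: bool = True) -> np.ndarray:
        """Total time spent per state.

        With ``censored=False``, censored sojourns are excluded (the exposure
        appropriate to rate estimation).
        """
        soj = self.sojourns
        if not censored:
            soj = soj * self.uncensored
        return np.bincount(self.states, weights=soj, minlength=n_states)


@dataclass
class TransitionCounts:
    """Pooled pairwise jump counts and occupancy exposure for CTMC MLE.

    ``counts[i, j]`` is the number of observed i→j jumps whose source sojourn
    was fully observed; ``occupancy[i]`` is the matching exposure in seconds.
    """

    counts: np.ndarray
    occupancy: np.ndarray
    n_sequences: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        n = self.occupancy.size
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match occupancy length")
        if np.any(self.counts < 0) or np.any(self.counts.diagonal() != 0):
            raise ValueError("counts must be non-negative with zero diagonal")
        if np.any(self.occupancy < 0):
            raise ValueError("occupancy must be non-negative")

    @property
    def n_states(self) -> int:
        return self.occupancy.size

    @property
    def total_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class RegionPair:
    """Body and body+flagella pixel regions of one video frame.

    ``body`` (the inner region) must be contained in ``full`` (the outer
    region bounding the flagella).  Masks are boolean images on a common
    grid; ``pixel_size`` converts pixel units to micrometers.
    """

    body: np.ndarray
    full: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.body = np.asarray(self.body, dtype=bool)
        self.full = np.asarray(self.full, dtype=bool)
        if self.body.shape != self.full.shape or self.body.ndim != 2:
            raise ValueError("body and full must be 2-D masks of equal shape")
        if not self.body.any():
            raise ValueError("body region is empty")
        if np.any(self.body & ~self.full):
            raise ValueError("body region must be contained in the full region")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def flagellar(self) -> np.ndarray:
        """The flagellar annulus full\\body."""
        return self.full & ~self.body

    def to_labels(self) -> np.ndarray:
        """Label image: 0 background, 1 flagellar region, 2 body."""
        out = np.zeros(self.body.shape, dtype=np.uint8)
        out[self.flagellar] = 1
        out[self.body] = 2
        return out

    @classmethod
    def from_labels(cls, labels: np.ndarray, pixel_size: float = 1.0) -> "RegionPair":
        labels = np.asarray(labels)
        return cls(body=labels == 2, full=labels >= 1, pixel_size=pixel_size)


@dataclass
class ShapeSeries:
    """Flagella–body centroid separation λ(t) (um) over time."""

    times: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.times.shape != self.lam.shape or self.times.ndim != 1:
            raise ValueError("times and lam must be 1-D arrays of equal length")
        if np.any(self.lam < 0):
            raise ValueError("lambda is a norm and must be non-negative")
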