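"""End-to-end orchestration: tracks → speeds → gaits → CTMC → thermodynamics.

``run_pipeline`` chains the analysis stages into a single JSON-serializable
report.  The pipeline is a pure function of (configuration, input tracks,
seeds): identical inputs produce byte-identical reports.  Any stage failure
aborts with the stage name and the underlying cause.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import presets
from .core import Track
from .ctmc_inference import (
    embedded_chain,
    estimate_rate_matrix,
    expected_waiting_times,
    stationary_distribution,
)
from .gait_segmentation import (
    GaitThresholds,
    compute_speed,
    discretize_gaits,
    dwell_fractions,
    extract_transitions,
)
from .kinematics_features import event_triggered_average, fit_transition_profile
from .noneq_thermo import RegularizationConfig, noneq_report
from .synthetic_motility import SimulationConfig

logger = logging.getLogger("gaitflux")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Configuration of the full analysis pipeline.

    ``t_max`` is either the string ``"observed_max"`` (use the longest
    track in the cohort, the reference convention) or a fixed value in
    seconds.  ``min_dwell`` of None means two frame intervals.
    """

    thresholds: GaitThresholds = field(default_factory=GaitThresholds)
    min_dwell: float | None = None
    smoothing_window: int = 1
    t_max: float | str = "observed_max"
    simulation: SimulationConfig | None = None
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict[str, Any]:
        from .io import config_to_dict

        return {
            "thresholds": dataclasses.asdict(self.thresholds),
            "min_dwell": self.min_dwell,
            "smoothing_window": self.smoothing_window,
            "t_max": self.t_max,
            "simulation": config_to_dict(self.simulation) if self.simulation else None,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        from .io import config_from_dict

        return cls(
            thresholds=GaitThresholds(**d.get("thresholds", {})),
            min_dwell=d.get("min_dwell"),
            smoothing_window=d.get("smoothing_window", 1),
            t_max=d.get("t_max", "observed_max"),
            simulation=(
                config_from_dict(d["simulation"]) if d.get("simulation") else None
            ),
            seed=d.get("seed", 0),
            output_dir=d.get("output_dir", "."),
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _profile_fits(speeds, sequences) -> dict[str, Any]:
    """Event-triggered Gaussian (into-shock) and tanh (run→stop) fits.

    Returns None entries when a cohort lacks enough events — small cohorts
    are legitimate inputs for the CTMC stages alone.
    """
    shock_events = []
    runstop_events = []
    for idx, seq in enumerate(sequences):
        for m in range(1, seq.n_sojourns):
            t_jump = seq.boundaries[m]
            if seq.states[m] == presets.SHOCK:
                # center on the shock midpoint so pulse peaks align
                shock_events.append(
                    (idx, 0.5 * (seq.boundaries[m] + seq.boundaries[m + 1]))
                )
            if seq.states[m - 1] == presets.RUN and seq.states[m] == presets.STOP:
                runstop_events.append((idx, t_jump))
    out: dict[str, Any] = {"n_shock_events": len(shock_events),
                           "n_runstop_events": len(runstop_events)}
    if len(shock_events) >= 2:
        prof = event_triggered_average(speeds, shock_events, window=0.12)
        fit = fit_transition_profile(prof, kind="gaussian_pulse")
        out["shock_pulse"] = {
            "sigma_s": fit.width, "amplitude": fit.amplitude,
            "baseline": fit.baseline, "converged": fit.converged,
            "residual_rms": fit.residual_rms,
        }
    else:
        out["shock_pulse"] = None
    if len(runstop_events) >= 2:
        prof = event_triggered_average(speeds, runstop_events, window=4.0)
        fit = fit_transition_profile(prof, kind="tanh_switch")
        out["runstop_switch"] = {
            "tau_s": fit.width, "amplitude": fit.amplitude,
            "baseline": fit.baseline, "converged": fit.converged,
            "residual_rms": fit.residual_rms,
        }
    else:
        out["runstop_switch"] = None
    return out


def run_pipeline(config: PipelineConfig, tracks: Sequence[Track]) -> dict[str, Any]:
    """Run segment → fit-ctmc → noneq → features and assemble the report."""
    if not tracks:
        raise PipelineError("stage 'input' failed: no tracks provided")
    n_states = 3

    speeds = _stage("speed")(
        lambda: [compute_speed(tr, config.smoothing_window) for tr in tracks]
    )()
    logger.info("speed: %d tracks", len(tracks))

    sequences = _stage("segment")(
        lambda: [
            discretize_gaits(sp, config.thresholds, config.min_dwell,
                             sequence_id=tr.track_id)
            for sp, tr in zip(speeds, tracks)
        ]
    )()
    logger.info("segment: %d sequences, %d total sojourns",
                len(sequences), sum(s.n_sojourns for s in sequences))

    fractions = _stage("dwell")(lambda: dwell_fractions(sequences, n_states))()
    counts = _stage("transitions")(lambda: extract_transitions(sequences, n_states))()
    logger.info("transitions: %d pairwise jumps", counts.total_transitions)

    q_hat = _stage("fit-ctmc")(
        lambda: estimate_rate_matrix(counts, labels=presets.STATE_LABELS)
    )()
    pi_hat = _stage("stationary")(lambda: stationary_distribution(q_hat))()
    k_hat = _stage("embedded")(lambda: embedded_chain(q_hat))()
    waiting = _stage("waiting-times")(
        lambda: expected_waiting_times(q_hat, counts)
    )()

    if config.t_max == "observed_max":
        t_max = float(max(tr.duration for tr in tracks))
    else:
        t_max = float(config.t_max)
    noneq = _stage("noneq")(
        lambda: noneq_report(pi_hat, k_hat, RegularizationConfig(t_max=t_max))
    )()

    features = _stage("features")(lambda: _profile_fits(speeds, sequences))()

    report = {
        "n_tracks": len(tracks),
        "total_duration_s": float(sum(tr.duration for tr in tracks)),
        "t_max_s": t_max,
        "t_max_policy": config.t_max if isinstance(config.t_max, str) else "fixed",
        "seed": config.seed,
        "config": config.to_dict(),
        "transition_counts": counts.counts.tolist(),
        "occupancy_s": counts.occupancy.tolist(),
        "dwell_fractions": fractions.tolist(),
        "rate_matrix": q_hat.q.tolist(),
        "rate_matrix_se": q_hat.standard_error.tolist(),
        "stationary": pi_hat.pi.tolist(),
        "embedded_chain": k_hat.k.tolist(),
        "waiting_times_s": waiting.mean.tolist(),
        "waiting_times_se": (
            waiting.standard_error.tolist()
            if waiting.standard_error is not None else None
        ),
        "noneq": noneq.to_dict(),
        "features": features,
        "state_labels": list(presets.STATE_LABELS),
    }
    return report
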