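"""Published reference model for run-stop-shock motility.

The octoflagellate alga *Pyramimonas octopus* switches between three
stereotyped swimming gaits: long quiescent *stops*, forward *runs* with
breaststroke (puller) beating, and ultrafast *shocks* in which the flagella
are thrown in front of the cell and the swimming direction transiently
reverses.  Gait switching is well described by a three-state
continuous-time Markov chain whose generator was estimated from ~1e4 s of
cumulative high-speed tracking (1377 pairwise transitions from 233 cells).

This module stores that published model — the rate matrix, the stationary
distribution, the embedded jump chain, the speed-band cutoffs used to
discretize tracks, and the emission parameters of the three gaits — as the
default parameterization of the synthetic generator and the reference
values of the analysis pipeline.
"""

from __future__ import annotations

import numpy as np

#: State codes shared across the package.
STOP, RUN, SHOCK = 0, 1, 2

#: State labels, indexed by state code.
STATE_LABELS: tuple[str, str, str] = ("stop", "run", "shock")

#: Published infinitesimal generator (s^-1), rows/cols ordered stop, run, shock.
#: Rounded to the precision at which it was reported (3 decimals / 4 s.f.).
REFERENCE_Q: np.ndarray = np.array(
    [
        [-0.132, 0.008, 0.124],
        [0.281, -1.330, 1.049],
        [0.0, 19.77, -19.77],
    ]
)

#: Published stationary distribution (stop, run, shock).
REFERENCE_PI: np.ndarray = np.array([0.6666, 0.3126, 0.0208])

#: Published embedded-chain jump probabilities.  Row 0 was evidently computed
#: from unrounded rates (0.008/0.132 gives 0.0606, not 0.0582); the published
#: figures are kept verbatim here.
REFERENCE_K: np.ndarray = np.array(
    [
        [0.0, 0.0582, 0.9418],
        [0.2112, 0.0, 0.7888],
        [0.0, 1.0, 0.0],
    ]
)

#: Maximum single-track duration (s) of the reference data set; bounds the
#: rate assigned to never-observed transitions.
T_MAX_S: float = 78.17

#: Speed cutoffs (um/s) of the three-state discretization:
#: stop [0, 40), run [40, 500), shock [500, inf).
STOP_SPEED_MAX_UMS: float = 40.0
RUN_SPEED_MAX_UMS: float = 500.0

#: Gait emission parameters (um/s unless noted).
RUN_SPEED_MEAN_UMS: float = 428.0
RUN_SPEED_SD_UMS: float = 64.0
SHOCK_PEAK_MEAN_UMS: float = 1712.0
SHOCK_PEAK_SD_UMS: float = 392.0
SHOCK_WIDTH_SIGMA_S: float = 8.6e-3
RUNSTOP_TAU_S: float = 0.640
STARTUP_RELAXATION_S: float = 0.050

#: Cell-body geometry (um): mean length and width of the reference cells.
BODY_LENGTH_UM: float = 17.05
BODY_WIDTH_UM: float = 9.05

#: Flagellar bending rigidity (pN um^2) used in the contact-force formula.
FLAGELLAR_EI_PN_UM2: float = 840.0


def reference_rate_matrix():
    """Return the published generator as a validated :class:`RateMatrix`."""
    from .ctmc_inference import RateMatrix

    return RateMatrix(REFERENCE_Q.copy(), labels=STATE_LABELS)
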