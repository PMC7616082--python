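# Methods

## The gait process and its estimation

Swimming behavior is reduced to a three-state jump process
X(t) ∈ {stop, run, shock} by thresholding instantaneous speed at
40 and 500 μm/s.  The published band edges overlap at the cutoffs
("0–40", "40–500", "≥500"); we resolve them as half-open intervals with
the boundary assigned upward — a deterministic convention that differs
from any alternative only on a measure-zero set of speeds.  Speeds are
estimated from positions by central differences (`numpy.gradient`), with
one-sided differences at track endpoints and an optional centered
moving-average smoother.

Label chatter shorter than `min_dwell` (default: two frame intervals) is
merged into the preceding state.  Shock labels bracketed by two *distinct*
states are exempt — a genuine stop→shock→run event can be arbitrarily
brief — while a sub-dwell blip inside a single state is treated as
threshold noise.  A side effect worth knowing: a genuinely sub-dwell run
sandwiched between a shock and a stop is absorbed into the shock,
manufacturing a shock→stop transition that the underlying process forbids.
At the reference rates this touches ~0.3% of runs; it is invisible to the
rate and occupancy estimates but can dominate the *plug-in* entropy
production of a small cohort, because a single spurious count turns an
exactly-zero jump probability into a tiny positive one with a large
log-ratio.  This is the familiar small-count pathology of entropy
estimators, not a bug in the arithmetic; cohorts of a few thousand seconds
make it rare, and the transition-count matrix in every report makes it
auditable.

The generator MLE is q̂_ij = N_ij/R_i with standard errors √N_ij/R_i.
Every observed jump counts and every observed second of occupancy is
exposure.  First and last sojourns of a track are flagged censored: their
*durations* are excluded from sojourn-time statistics (they are
truncated), but their exposure and observed exits remain valid for rate
estimation — the residual life of an exponential sojourn is exponential
with the same rate, and a right-censored sojourn contributes exposure
without an event.  The alternative "completed sojourns only" estimator is
length-biased against long sojourns whenever dwell times are comparable to
track durations, which is exactly the stop-state regime here (7.6 s mean
dwell vs 0.5–80 s tracks); we measured a ~0.06 bias in the stop occupancy
of a 200-track cohort under that estimator, against < 0.02 for the
standard one.

The Markov assumption is checked by a Lilliefors-type exponentiality test
on uncensored sojourns: the KS distance to an exponential with the fitted
(sample-mean) rate is compared against a parametric-bootstrap critical
value (default 999 seeded resamples, each refitted), which accounts for
the estimated parameter.  States with fewer than 10 uncensored sojourns
are skipped, not failed.

## Nonequilibrium diagnostics

Fluxes J_ij = π_i k_ij − π_j k_ji are antisymmetric by construction.  The
entropy-production rate is computed in its stationary form

Ṡ = ½ Σ_{i≠j} (π_i k_ij − π_j k_ji) ln(k_ij/k_ji),

together with the Schnakenberg affinity form ½ Σ J_ij A_ij,
A_ij = ln(π_i k_ij / π_j k_ji), as a cross-check field.  The two coincide
when π is the stationary law of the jump chain K; with π taken as the
*CTMC* stationary law (the convention of the reference analysis, and the
only one that reproduces its reported Ṡ) they generally differ, and the
stationary form is the quoted value.  An index-swapped affinity variant
ln(π_j k_ij / π_i k_ji) appears in some presentations; it is computed and
reported as a diagnostic but not used, since only the standard form is
termwise non-negative at chain stationarity.  Pairs with zero probability
in both directions contribute exactly zero (0·ln(0/0) := 0 by the flux
limit); a one-sided zero is an error that directs the caller to
regularization.  Ṡ mixes per-jump probabilities with stationary
occupancies and is reported as dimensionless.

Never-observed reactions: a zero k_ji whose reverse k_ij is positive is
replaced by 1/(π_j·T_max) — one unobserved jump per longest track
(duration T_max), weighted by how often the source state j is visited.
The source-state convention is deliberate: with the reference inputs
(π = (0.6666, 0.3126, 0.0208), published k values, T_max = 78.17 s) it
gives k_shock→stop = 0.6150 and Ṡ = 0.2436, consistent with the reported
0.249 at the precision of the printed inputs, whereas a destination-state
reading is off by an order of magnitude.  Rows are not re-normalized after
replacement (a flag enables it for sensitivity checks), and pairs that are
zero in both directions are left untouched — regularizing a structurally
absent reaction would invent dynamics.  T_max defaults to the observed
maximum track duration in the cohort, with a fixed override for
reproducing the reference value.

## The synthetic generator

`synthetic_motility` emulates the statistical structure the analysis
assumes, with the published values as defaults:

| parameter | default | meaning |
|---|---|---|
| `rate_matrix` | reference Q (s⁻¹) | gait-switching generator |
| `run_speed_mean/sd` | 428 / 64 μm/s | run-band emission |
| `shock_peak_mean/sd` | 1712 / 392 μm/s | per-shock pulse peak draw |
| `shock_width_sigma` | 8.6 ms | stereotyped pulse scale, frame-resolution bound |
| `runstop_tau` | 640 ms | run→stop tanh relaxation |
| `startup_relaxation` | 50 ms | post-shock/startup relaxation, OU correlation time |
| `stop_speed_sd` | 5 μm/s | residual stop jitter |
| `frame_interval` | 0.5 ms | sampling grid (must resolve the pulse width) |
| `rotational_diffusion` | 0.3 rad²/s | run heading diffusion (package choice) |
| `stop_curvature_ramp` | 3 rad/s | pre-stop curvature ramp (package choice) |

Gait sequences are exact Gillespie realizations; the final sojourn is
truncated at the horizon and flagged censored.  Cohorts draw track
durations log-uniformly on 0.5–80 s, the span of the reference recordings.

Two emission choices depart from the most literal reading of the
stereotyped profiles, both forced by self-consistency between the
generator and the threshold segmentation it feeds:

1. **Shock pulses are sojourn-scaled.**  Each shock is a Gaussian pulse
   whose width is set per event, σ_n = s_n / (2√(2 ln(peak_n/500))), so
   the speed crosses the 500 μm/s cutoff exactly at the jump times.  A
   fixed 8.6 ms pulse peaking at ~1712 μm/s stays above the cutoff for
   only ~27 ms, so segmenting such output would recover a shock exit rate
   near 37 s⁻¹ instead of the 19.77 s⁻¹ that generated it — the generator
   would contradict its own rate matrix.  The configured
   `shock_width_sigma` remains the stereotyped scale used for isolated
   pulse synthesis and as the lower bound on frame resolution.
2. **Run-band speeds are confined to the band.**  Run fluctuations are a
   mean-reverting (Ornstein–Uhlenbeck) process with stationary sd
   64 μm/s and correlation time 50 ms, clipped into [40, 498] μm/s.  An
   unclipped Gaussian tail would put ~13% of run time above the shock
   cutoff, whereas the empirical speed histogram assigns only ~0.6% of
   time above it (all of it shocks); the published ±64 describes spread
   across events, not a license for band-crossing excursions.  Near the
   run→stop crossing the noise envelope is scaled with the squared tanh
   profile so fluctuations do not displace the threshold crossing.

The run→stop deceleration is a tanh with τ = 640 ms positioned so the
profile crosses 40 μm/s exactly at the jump time; runs shorter than the
relaxation window compress τ proportionally (0.45× the sojourn) so short
runs still start near full speed.  Consequently the *cohort-level*
event-triggered run→stop fit recovers 640 ms only for long runs; the
parameter-recovery guarantees are stated for the stereotyped profiles
themselves.  Stops emit |Gaussian| jitter with per-frame isotropic
displacement directions, so the centroid jiggles without net drift.
Headings diffuse during runs, reverse during shocks (body axis ê_R held,
motion antiparallel: D = −1), randomize on shock exit, and curl under a
ramped angular velocity during the final pre-stop window.  Region masks
place an elliptical body (17.05 × 9.05 μm) along ê_R with a flagellar lobe
behind the body in runs, sweeping to the front across each shock (so shape
change lags the speed pulse), and hugging the body in stops.

What the generator does **not** emulate: 3D helical motion and self-spin,
hydrodynamic interactions, localization noise on positions, photoresponse,
flagellum-resolved waveforms, and intensity-based mask segmentation.
Passing tests therefore certify the *analysis chain* — segmentation, CTMC
inference, thermodynamics, profile fitting — under the published
statistical structure, not robustness to raw-microscopy artifacts.

## Numerical choices

* Matrix exponentials use dense scaling-and-squaring (`scipy.linalg.expm`);
  tiny negative entries are clipped and rows re-normalized.  The
  Chapman–Kolmogorov contract is 1e-8.
* Irreducibility is verified by strongly connected components of the
  off-diagonal support graph before any stationary-law computation; a
  reducible generator raises with the component partition.
* The stationary law is the normalized basis vector of the left null space
  (`scipy.linalg.null_space`), clipped at zero and re-normalized.
* Profile fits use analytic initialization — moment/half-max width for the
  Gaussian, half-crossing and local slope for the tanh — so they are
  deterministic; non-convergence is reported via a flag, never clamped.
* Degenerate inputs are rejected eagerly with specific messages: absorbing
  states, empty sequences, non-monotone times, negative speeds, empty
  flagellar regions, disjoint time supports.

## Problem sizes used in validation

Deterministic reference values (stationary law, waiting times, embedded
chain, entropy production, cycle products) are recomputed directly from
the published generator and probabilities.  The stochastic rate-recovery
check simulates 1e5 s of the reference process (50 tracks × 2000 s at the
default 0.5 ms frames, ~41,000 shock→run events, relative standard error
~0.5%); the shock exit rate is recovered within 5% and dwell fractions
within 0.01 of the stationary law.  Profile-fit calibration uses 100
seeded noisy replicates per profile kind.  Exponentiality calibration
checks that the bootstrap test's rejection rate over 100 seeds stays in a
3σ binomial band around its nominal level — a ≥95%-pass assertion at
α = 0.05 would fail a perfectly calibrated test about half the time.

## Known limitations

* The entropy-production estimate is a plug-in functional of estimated
  probabilities; it is biased upward for small counts and hypersensitive
  to rare spurious transitions (see the debounce note above).  No
  trajectory-level or coarse-graining-corrected estimators are provided.
* The speed cutoffs are treated as fixed constants of the analysis; their
  subjectivity is acknowledged and exposed through configuration, but no
  canonical sensitivity analysis is prescribed.
* `contact_force` is a calculator for F = 3EIδ/L³; deflection and length
  must be supplied by the user, as no reference geometry pins them down.
* Mask synthesis invents the lobe geometry (only body dimensions are
  published); the shape metric is exact for whatever masks it is given,
  to half-pixel accuracy in centroid placement.
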