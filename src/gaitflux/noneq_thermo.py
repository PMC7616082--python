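"""Broken detailed balance on the gait reaction graph.

At stationarity the gait network carries net probability fluxes
``J_ij = π_i k_ij − π_j k_ji`` between states.  Detailed balance (all
J_ij = 0) is equivalent, by the Kolmogorov criterion, to equal forward and
reverse jump-probability products around every cycle; its violation is
quantified by the entropy-production rate

    Ṡ = ½ Σ_{i≠j} (π_i k_ij − π_j k_ji) · ln(k_ij / k_ji)  ≥ 0,

the stationary form of the Schnakenberg network expression
``Ṡ = ½ Σ J_ij A_ij`` with affinities ``A_ij = ln(π_i k_ij / π_j k_ji)``.
Both forms coincide when π is stationary for the jump chain; both are
computed and reported.  Ṡ is dimensionless here (per-jump probabilities
against stationary occupancies); only its positivity and magnitude are
interpreted.

Transitions never observed in a finite recording make k_ji = 0 and Ṡ
diverge.  Following the reference analysis, a never-observed jump out of
state ``j`` is assigned the smallest resolvable probability
``k_ji = 1 / (π_j · T_max)``, where T_max is the maximum single-track
duration — one such jump per longest track, weighted by how often the
source state is visited.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ctmc_inference import EmbeddedChain, StationaryDistribution

__all__ = [
    "RegularizationConfig",
    "Replacement",
    "RegularizedChain",
    "CycleTest",
    "EntropyProductionResult",
    "NoneqSummary",
    "stationary_fluxes",
    "kolmogorov_criterion",
    "regularize_unobserved",
    "entropy_production",
    "noneq_report",
]


@dataclass(frozen=True)
class RegularizationConfig:
    """Policy for never-observed transitions.

    Parameters
    ----------
    t_max
        Maximum single-track duration in seconds (the reference analysis
        used 78.17 s).
    enabled
        If False, zero entries with an observed reverse raise instead.
    source_state_convention
        If True (default), the replacement for a zero entry k_ji uses the
        stationary probability of the *source* state j of the unobserved
        jump: k_ji = 1/(π_j T_max).  The alternative (destination-state)
        convention is provided only for sensitivity checks; with the
        published inputs it misses the reported entropy production by an
        order of magnitude.
    renormalize
        Re-normalize rows after replacement (off by default; replacements
        are tiny and the reference analysis shows no renormalization).
    """

    t_max: float = 78.17
    enabled: bool = True
    source_state_convention: bool = True
    renormalize: bool = False

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")


@dataclass(frozen=True)
class Replacement:
    """Record of one regularized entry."""

    source: int
    destination: int
    value: float


@dataclass
class RegularizedChain:
    """An embedded chain with unobserved transitions regularized."""

    chain: EmbeddedChain
    replacements: tuple[Replacement, ...]


@dataclass
class CycleTest:
    """Forward/reverse jump-probability products around one cycle."""

    cycle: tuple[int, ...]
    forward: float
    reverse: float
    violated: bool


@dataclass
class EntropyProductionResult:
    """Entropy-production rate with its affinity-form cross-check."""

    value: float
    affinity_form: float
    pair_terms: np.ndarray

    def __float__(self) -> float:
        return float(self.value)


def stationary_fluxes(
    pi: StationaryDistribution | np.ndarray, K: EmbeddedChain | np.ndarray
) -> np.ndarray:
    """Net stationary fluxes J_ij = π_i k_ij − π_j k_ji (antisymmetric)."""
    p = np.asarray(pi, dtype=float)
    k = np.asarray(K, dtype=float)
    if k.shape != (p.size, p.size):
        raise ValueError("pi and K dimensions disagree")
    flow = p[:, None] * k
    return flow - flow.T


def kolmogorov_criterion(
    K: EmbeddedChain | np.ndarray,
    cycle: Sequence[int],
    tolerance: float | None = None,
) -> CycleTest:
    """Compare forward and reverse jump products around a closed cycle.

    ``cycle`` lists distinct states, e.g. ``(0, 1, 2)`` for 0→1→2→0; a
    trailing repeat of the first state is accepted.  Detailed balance
    requires forward == reverse around every cycle.
    """
    cyc = list(cycle)
    if len(cyc) > 1 and cyc[0] == cyc[-1]:
        cyc = cyc[:-1]
    if len(cyc) < 3:
        raise ValueError("a cycle must visit at least 3 distinct states")
    if len(set(cyc)) != len(cyc):
        raise ValueError("cycle must not repeat intermediate states")
    k = np.asarray(K, dtype=float)
    forward = 1.0
    reverse = 1.0
    for a, b in zip(cyc, cyc[1:] + cyc[:1]):
        forward *= k[a, b]
        reverse *= k[b, a]
    if tolerance is None:
        tolerance = 1e-12 * max(1.0, reverse)
    return CycleTest(
        cycle=tuple(cyc),
        forward=forward,
        reverse=reverse,
        violated=bool(abs(forward - reverse) > tolerance),
    )


def regularize_unobserved(
    K: EmbeddedChain,
    pi: StationaryDistribution | np.ndarray,
    config: RegularizationConfig | None = None,
) -> RegularizedChain:
    """Replace never-observed reverse jumps by their resolution floor.

    Only zero off-diagonal entries whose reverse entry is positive are
    touched — those are the "apparently irreversible" reactions; a pair
    with zero probability in both directions is structurally absent and
    contributes nothing to the entropy production.
    """
    config = config or RegularizationConfig()
    p = np.asarray(pi, dtype=float)
    k = np.asarray(K, dtype=float).copy()
    n = k.shape[0]
    replacements: list[Replacement] = []
    for j in range(n):
        for i in range(n):
            if i == j or k[j, i] > 0 or k[i, j] <= 0:
                continue
            src = j if config.source_state_convention else i
            if p[src] <= 0:
                raise ValueError(
                    f"state {src} has zero stationary probability; "
                    "cannot regularize its unobserved transition"
                )
            value = 1.0 / (p[src] * config.t_max)
            k[j, i] = value
            replacements.append(Replacement(source=j, destination=i, value=value))
    if config.renormalize and replacements:
        k /= k.sum(axis=1, keepdims=True)
    # Replacement entries break exact row-stochasticity by design; bypass
    # the EmbeddedChain row-sum check by renormalizing only when asked.
    chain = EmbeddedChain.__new__(EmbeddedChain)
    chain.k = k
    chain.labels = getattr(K, "labels", None)
    return RegularizedChain(chain=chain, replacements=tuple(replacements))


def entropy_production(
    pi: StationaryDistribution | np.ndarray,
    K: EmbeddedChain | RegularizedChain | np.ndarray,
) -> EntropyProductionResult:
    """Entropy-production rate Ṡ of the stationary gait network.

    ``value`` is the stationary form ½ Σ (π_i k_ij − π_j k_ji) ln(k_ij/k_ji);
    ``affinity_form`` is ½ Σ J_ij ln(π_i k_ij / π_j k_ji), identical when π
    is stationary for K and reported as a cross-check.  Pairs with zero
    probability in both directions contribute exactly 0; a single-sided zero
    is an error directing the caller to :func:`regularize_unobserved`.
    """
    if isinstance(K, RegularizedChain):
        K = K.chain
    p = np.asarray(pi, dtype=float)
    k = np.asarray(K, dtype=float)
    n = p.size
    if k.shape != (n, n):
        raise ValueError("pi and K dimensions disagree")
    terms = np.zeros((n, n))
    aff_terms = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            kij, kji = k[i, j], k[j, i]
            if kij == 0 and kji == 0:
                continue
            if kij == 0 or kji == 0:
                raise ValueError(
                    f"one-sided zero jump probability for pair ({i}, {j}); "
                    "apply regularize_unobserved first"
                )
            flux = p[i] * kij - p[j] * kji
            terms[i, j] = flux * np.log(kij / kji)
            aff_terms[i, j] = flux * np.log((p[i] * kij) / (p[j] * kji))
    return EntropyProductionResult(
        value=0.5 * float(terms.sum()),
        affinity_form=0.5 * float(aff_terms.sum()),
        pair_terms=terms,
    )


@dataclass
class NoneqSummary:
    """Bundle of all nonequilibrium diagnostics of one fitted model."""

    pi: np.ndarray
    k: np.ndarray
    fluxes: np.ndarray
    affinities: np.ndarray
    affinities_swapped: np.ndarray
    entropy_production: float
    entropy_production_affinity_form: float
    cycles: list[CycleTest]
    replacements: tuple[Replacement, ...]
    t_max: float
    labels: tuple[str, ...] | None = None

    @property
    def any_cycle_violated(self) -> bool:
        return any(c.violated for c in self.cycles)

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "k": self.k.tolist(),
            "fluxes": self.fluxes.tolist(),
            "affinities": self.affinities.tolist(),
            "affinities_swapped": self.affinities_swapped.tolist(),
            "entropy_production": self.entropy_production,
            "entropy_production_affinity_form": self.entropy_production_affinity_form,
            "cycles": [
                {
                    "cycle": list(c.cycle),
                    "forward": c.forward,
                    "reverse": c.reverse,
                    "violated": c.violated,
                }
                for c in self.cycles
            ],
            "replacements": [
                {"source": r.source, "destination": r.destination, "value": r.value}
                for r in self.replacements
            ],
            "t_max": self.t_max,
            "labels": list(self.labels) if self.labels else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoneqSummary":
        return cls(
            pi=np.asarray(d["pi"]),
            k=np.asarray(d["k"]),
            fluxes=np.asarray(d["fluxes"]),
            affinities=np.asarray(d["affinities"]),
            affinities_swapped=np.asarray(d["affinities_swapped"]),
            entropy_production=d["entropy_production"],
            entropy_production_affinity_form=d["entropy_production_affinity_form"],
            cycles=[
                CycleTest(tuple(c["cycle"]), c["forward"], c["reverse"], c["violated"])
                for c in d["cycles"]
            ],
            replacements=tuple(
                Replacement(r["source"], r["destination"], r["value"])
                for r in d["replacements"]
            ),
            t_max=d["t_max"],
            labels=tuple(d["labels"]) if d.get("labels") else None,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "NoneqSummary":
        return cls.from_dict(json.loads(s))


def _log_ratio_matrix(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = (num > 0) & (den > 0)
    out[ok] = np.log(num[ok] / den[ok])
    np.fill_diagonal(out, 0.0)
    return out


def noneq_report(
    pi: StationaryDistribution | np.ndarray,
    K: EmbeddedChain,
    config: RegularizationConfig | None = None,
) -> NoneqSummary:
    """Full nonequilibrium summary: fluxes, affinities, cycles, Ṡ.

    The Kolmogorov criterion is evaluated on the *raw* (pre-regularization)
    chain for every 3-state cycle; the entropy production uses the
    regularized chain when regularization is enabled and needed.
    """
    config = config or RegularizationConfig()
    p = np.asarray(pi, dtype=float)
    raw_k = np.asarray(K, dtype=float)
    n = p.size
    cycles = [
        kolmogorov_criterion(raw_k, combo)
        for combo in itertools.combinations(range(n), 3)
    ]
    if config.enabled:
        reg = regularize_unobserved(K, p, config)
        k_used = np.asarray(reg.chain, dtype=float)
        replacements = reg.replacements
    else:
        k_used = raw_k
        replacements = ()
    sdot = entropy_production(p, k_used)
    flow = p[:, None] * k_used
    return NoneqSummary(
        pi=p,
        k=k_used,
        fluxes=stationary_fluxes(p, k_used),
        affinities=_log_ratio_matrix(flow, flow.T),
        affinities_swapped=_log_ratio_matrix(
            p[None, :] * k_used, (p[:, None] * k_used.T)
        ),
        entropy_production=sdot.value,
        entropy_production_affinity_form=sdot.affinity_form,
        cycles=cycles,
        replacements=replacements,
        t_max=config.t_max,
        labels=getattr(K, "labels", None),
    )
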