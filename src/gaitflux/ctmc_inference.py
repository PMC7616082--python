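"""Continuous-time Markov chain estimation and manipulation.

The gait process X(t) ∈ {stop, run, shock} is modeled as an irreducible
CTMC with infinitesimal generator Q = {q_ij}: off-diagonal entries are
transition rates (s⁻¹), q_ii = −Σ_{j≠i} q_ij, sojourn times in state i are
exponential with rate −q_ii, and the successor state is drawn from the
embedded jump chain k_ij = q_ij / Σ_{l≠i} q_il.  The transition-probability
matrix P(t) = exp(tQ) solves dP/dt = PQ, and the stationary distribution π
is the normalized zero-eigenvalue left eigenvector of Q.

Rates are estimated from segmented trajectories by the standard MLE
q̂_ij = N_ij / R_i — observed i→j jump counts over observed occupancy time —
with Poisson standard errors √N_ij / R_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm, null_space
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import GaitStateSequence, TransitionCounts

__all__ = [
    "RateMatrix",
    "TransitionMatrix",
    "StationaryDistribution",
    "EmbeddedChain",
    "WaitingTimes",
    "SojournTestResult",
    "ReducibleChainError",
    "estimate_rate_matrix",
    "transition_probability",
    "stationary_distribution",
    "embedded_chain",
    "expected_waiting_times",
    "sojourn_exponentiality_check",
]

_ROW_SUM_TOL = 1e-10


class ReducibleChainError(ValueError):
    """Raised when a chain is not irreducible; carries the SCC partition."""

    def __init__(self, components: list[list[int]]):
        self.components = components
        super().__init__(
            "generator is not irreducible; strongly connected components: "
            f"{components}"
        )


@dataclass
class RateMatrix:
    """A conservative generator Q (s⁻¹) with optional standard errors."""

    q: np.ndarray
    labels: Sequence[str] | None = None
    standard_error: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        n = self.q.shape[0]
        if self.q.shape != (n, n) or n < 2:
            raise ValueError("rate matrix must be square with n >= 2")
        off = self.q[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        rowsum = self.q.sum(axis=1)
        if np.any(np.abs(rowsum) > _ROW_SUM_TOL * max(1.0, np.abs(self.q).max())):
            raise ValueError("rows of a conservative generator must sum to zero")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must match matrix size")
        if self.standard_error is not None:
            self.standard_error = np.asarray(self.standard_error, dtype=float)
            if self.standard_error.shape != self.q.shape:
                raise ValueError("standard_error must match q shape")

    def __eq__(self, other) -> bool:
        if not isinstance(other, RateMatrix):
            return NotImplemented
        return (
            np.array_equal(self.q, other.q)
            and self.labels == other.labels
            and (
                (self.standard_error is None) == (other.standard_error is None)
                and (
                    self.standard_error is None
                    or np.array_equal(self.standard_error, other.standard_error)
                )
            )
        )

    @property
    def n_states(self) -> int:
        return self.q.shape[0]

    @property
    def exit_rates(self) -> np.ndarray:
        """Total exit rate −q_ii per state (s⁻¹)."""
        return -np.diag(self.q)

    @property
    def absorbing_states(self) -> np.ndarray:
        """Indices of states with no positive outgoing rate."""
        return np.flatnonzero(self.exit_rates <= 0)


@dataclass
class TransitionMatrix:
    """P(t): row-stochastic transition probabilities at horizon t (s)."""

    p: np.ndarray
    t: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(self.p.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("rows of P(t) must sum to 1")


@dataclass
class StationaryDistribution:
    """π: the long-time occupancy probabilities of an irreducible CTMC."""

    pi: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1:
            raise ValueError("pi must be a vector")
        if np.any(self.pi < -1e-12):
            raise ValueError("pi entries must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must sum to 1")
        self.pi = np.clip(self.pi, 0.0, None)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.pi, dtype=dtype)


@dataclass
class EmbeddedChain:
    """Jump-chain probabilities k_ij (zero diagonal, rows sum to 1)."""

    k: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        n = self.k.shape[0]
        if self.k.shape != (n, n):
            raise ValueError("embedded chain must be square")
        if np.any(np.abs(np.diag(self.k)) > 1e-12):
            raise ValueError("embedded chain has zero diagonal by definition")
        if np.any(self.k < -1e-12) or np.any(self.k > 1 + 1e-12):
            raise ValueError("jump probabilities must lie in [0, 1]")
        if np.any(np.abs(self.k.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("rows of the embedded chain must sum to 1")

    @property
    def n_states(self) -> int:
        return self.k.shape[0]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.k, dtype=dtype)


@dataclass
class WaitingTimes:
    """Per-state expected sojourn times −1/q_ii (s)."""

    mean: np.ndarray
    standard_error: np.ndarray | None = None


@dataclass
class SojournTestResult:
    """Outcome of the exponentiality check for one state's sojourns."""

    state: int
    n: int
    mean: float
    ks_statistic: float
    critical_value: float
    p_value: float
    alpha: float
    passed: bool
    skipped: bool = False


def estimate_rate_matrix(
    counts: TransitionCounts | np.ndarray,
    occupancy: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
) -> RateMatrix:
    """Maximum-likelihood generator estimate q̂_ij = N_ij / R_i.

    Parameters
    ----------
    counts
        Either a :class:`TransitionCounts` bundle or a raw square count
        matrix (then ``occupancy`` is required).
    occupancy
        Observed time per state in seconds (exposure for the rate MLE).

    Returns
    -------
    RateMatrix
        The estimate with Poisson standard errors ``√N_ij / R_i`` attached.
        States never observed (zero occupancy, zero counts) get a zero row.

    Raises
    ------
    ValueError
        If some state has outgoing counts but zero occupancy (inconsistent).
    """
    if isinstance(counts, TransitionCounts):
        n_mat, occ = counts.counts, counts.occupancy
    else:
        if occupancy is None:
            raise ValueError("occupancy is required with a raw count matrix")
        n_mat = np.asarray(counts)
        occ = np.asarray(occupancy, dtype=float)
    n = occ.size
    q = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        if occ[i] > 0:
            q[i] = n_mat[i] / occ[i]
            se[i] = np.sqrt(n_mat[i]) / occ[i]
        elif n_mat[i].sum() > 0:
            raise ValueError(
                f"state {i} has outgoing transitions but zero occupancy time"
            )
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    np.fill_diagonal(se, 0.0)
    return RateMatrix(q, labels=labels, standard_error=se)


def transition_probability(Q: RateMatrix, t: float) -> TransitionMatrix:
    """P(t) = exp(tQ) via scaling-and-squaring (dense ``expm``)."""
    if t < 0:
        raise ValueError("time horizon must be non-negative")
    p = expm(Q.q * t)
    # expm can leave tiny negative entries; clean and re-normalize rows.
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return TransitionMatrix(p, t=float(t))


def _strongly_connected(Q: np.ndarray) -> list[list[int]]:
    support = csr_matrix((Q > 0).astype(np.int8))
    n_comp, member = connected_components(support, directed=True, connection="strong")
    return [list(np.flatnonzero(member == c)) for c in range(n_comp)]


def stationary_distribution(Q: RateMatrix) -> StationaryDistribution:
    """Normalized left null vector of Q.

    Irreducibility is verified first on the off-diagonal support graph; a
    reducible generator raises :class:`ReducibleChainError` listing the
    strongly connected components.
    """
    comps = _strongly_connected(Q.q)
    if len(comps) > 1:
        raise ReducibleChainError(comps)
    ns = null_space(Q.q.T)
    if ns.shape[1] != 1:  # pragma: no cover - excluded by irreducibility
        raise ValueError("stationary distribution is not unique")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return StationaryDistribution(pi, labels=Q.labels)


def embedded_chain(Q: RateMatrix) -> EmbeddedChain:
    """Row-normalized off-diagonal rates k_ij = q_ij / Σ_{l≠i} q_il."""
    exits = Q.exit_rates
    if np.any(exits <= 0):
        raise ValueError(
            f"absorbing state(s) {list(Q.absorbing_states)}: "
            "embedded chain undefined without outgoing rates"
        )
    k = Q.q / exits[:, None]
    np.fill_diagonal(k, 0.0)
    return EmbeddedChain(k, labels=Q.labels)


def expected_waiting_times(
    Q: RateMatrix, counts: TransitionCounts | np.ndarray | None = None
) -> WaitingTimes:
    """Mean sojourn −1/q_ii per state; SE = mean/√(exit count) if counts given."""
    exits = Q.exit_rates
    if np.any(exits <= 0):
        raise ValueError("every state needs a strictly negative diagonal rate")
    mean = 1.0 / exits
    se = None
    if counts is not None:
        c = counts.counts if isinstance(counts, TransitionCounts) else np.asarray(counts)
        n_exit = c.sum(axis=1).astype(float)
        with np.errstate(divide="ignore"):
            se = np.where(n_exit > 0, mean / np.sqrt(np.maximum(n_exit, 1)), np.inf)
    return WaitingTimes(mean=mean, standard_error=se)


def _ks_exponential(samples: np.ndarray) -> float:
    """KS distance between samples and Exp(1/mean) with the mean estimated."""
    x = np.sort(samples)
    n = x.size
    cdf = 1.0 - np.exp(-x / x.mean())
    grid = np.arange(n, dtype=float)
    return float(np.max(np.maximum(cdf - grid / n, (grid + 1) / n - cdf)))


def sojourn_exponentiality_check(
    sequences: Iterable[GaitStateSequence],
    n_states: int | None = None,
    alpha: float = 0.05,
    n_boot: int = 999,
    min_samples: int = 10,
    seed: int = 0,
) -> list[SojournTestResult]:
    """Lilliefors-type exponentiality test for uncensored sojourn times.

    For each state, the KS distance between the sojourn sample and an
    exponential with the fitted (sample-mean) rate is compared against a
    parametric-bootstrap critical value that accounts for the estimated
    parameter (``n_boot`` seeded resamples, each refitted).  States with
    fewer than ``min_samples`` uncensored sojourns are skipped, not failed.
    """
    sequences = list(sequences)
    if n_states is None:
        n_states = int(max(seq.states.max() for seq in sequences)) + 1
    per_state: list[list[float]] = [[] for _ in range(n_states)]
    for seq in sequences:
        mask = seq.uncensored
        for s, d in zip(seq.states[mask], seq.sojourns[mask]):
            per_state[s].append(float(d))
    rng = np.random.default_rng(seed)
    results = []
    for s in range(n_states):
        x = np.asarray(per_state[s])
        if x.size < min_samples:
            results.append(
                SojournTestResult(s, x.size, float(x.mean()) if x.size else np.nan,
                                  np.nan, np.nan, np.nan, alpha,
                                  passed=False, skipped=True)
            )
            continue
        d_obs = _ks_exponential(x)
        # Bootstrap under H0; the statistic is scale-free so Exp(1) suffices.
        boot = rng.standard_exponential((n_boot, x.size))
        bsort = np.sort(boot, axis=1)
        cdf = 1.0 - np.exp(-bsort / bsort.mean(axis=1, keepdims=True))
        grid = np.arange(x.size, dtype=float)
        d_boot = np.max(
            np.maximum(cdf - grid / x.size, (grid + 1) / x.size - cdf), axis=1
        )
        crit = float(np.quantile(d_boot, 1.0 - alpha))
        p_val = float((1 + np.sum(d_boot >= d_obs)) / (n_boot + 1))
        results.append(
            SojournTestResult(
                state=s, n=x.size, mean=float(x.mean()), ks_statistic=d_obs,
                critical_value=crit, p_value=p_val, alpha=alpha,
                passed=d_obs <= crit,
            )
        )
    return results
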