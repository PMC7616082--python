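import numpy as np
import pytest

from gaitflux import presets
from gaitflux.ctmc_inference import EmbeddedChain, RateMatrix


@pytest.fixture(scope="session")
def ref_q() -> RateMatrix:
    """The published three-state generator (stop, run, shock)."""
    return presets.reference_rate_matrix()


@pytest.fixture(scope="session")
def ref_pi() -> np.ndarray:
    return presets.REFERENCE_PI.copy()


@pytest.fixture(scope="session")
def ref_k() -> EmbeddedChain:
    return EmbeddedChain(presets.REFERENCE_K.copy(), labels=presets.STATE_LABELS)


def random_generator(rng: np.random.Generator, n: int = 3) -> RateMatrix:
    """A random irreducible conservative generator with O(1) rates."""
    q = rng.uniform(0.1, 2.0, (n, n))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q)


def reversible_chain(rng: np.random.Generator, n: int = 3) -> EmbeddedChain:
    """A detailed-balanced jump chain (row-normalized symmetric weights)."""
    s = rng.uniform(0.2, 2.0, (n, n))
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)
    return EmbeddedChain(s / s.sum(axis=1, keepdims=True))


def chain_stationary(k: np.ndarray) -> np.ndarray:
    """Stationary distribution of a discrete jump chain (left eigenvector)."""
    vals, vecs = np.linalg.eig(k.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()
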