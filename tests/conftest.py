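import numpy as np
import pytest

from helpmarket import AgentPopulation, ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def defaults():
    """Default market at perfect matching: m = 1, x = 0.5, k = 0, z = 1."""
    return ModelParams(N=100, m=1.0, x=0.5, k=0.0, z=1.0)


def brute_force_help_received(h: np.ndarray, k: float, z: float) -> np.ndarray:
    """Per-source share enumeration, the independent allocation oracle.

    Every source j splits its dispensed help h_j + k over the other
    individuals in proportion to their weights (h_i + k)**z; a source whose
    recipients all have zero weight splits equally.
    """
    n = h.size
    w = (h + k) ** z
    r = np.zeros(n)
    for j in range(n):
        weights = np.array([w[i] if i != j else 0.0 for i in range(n)])
        total = weights.sum()
        if total > 0:
            shares = weights / total
        else:
            shares = np.array([1.0 / (n - 1) if i != j else 0.0 for i in range(n)])
        r += (h[j] + k) * shares
    return r


@pytest.fixture
def brute_force():
    return brute_force_help_received
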