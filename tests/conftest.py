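import numpy as np
import pytest

from clomix.panel import CloneFrequencies, CountsPanel, MutationPrior


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_panel(rng):
    """4 loci × 3 subsections of modest random counts."""
    M, S = 4, 3
    N = rng.integers(5, 30, size=(M, S))
    X = np.minimum(rng.integers(0, 10, size=(M, S)), N)
    return CountsPanel(
        X=X, N=N,
        loci=[f"l{i}" for i in range(M)],
        subsections=["normal"] + [f"t{j}" for j in range(1, S)],
    )


def random_parameters(C, S, rng, theta=None):
    """A random valid (CloneFrequencies, MutationPrior) pair."""
    P = rng.uniform(size=(C, S))
    P /= P.sum(axis=0, keepdims=True)
    low = P[0] < 0.05
    if low.any():
        P[1:, low] *= (1 - 0.05) / P[1:, low].sum(axis=0, keepdims=True)
        P[0, low] = 0.05
    if theta is None:
        theta = np.concatenate([[0.0], rng.uniform(0.1, 0.9, size=C - 1)])
    return CloneFrequencies(P), MutationPrior(np.asarray(theta, dtype=float))
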