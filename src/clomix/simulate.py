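"""Synthetic multi-section read-count data.

Emulates the targeted deep-sequencing setting: per-subsection coverage is
multinomial over loci at a chosen mean depth, clone genotypes are Bernoulli
bits, clone frequencies are uniform draws normalized to a simplex per
subsection (with the normal subsection pinned to the pure-normal vector),
and variant read counts are binomial given the implied variant-read
probability.  Optional noise flips each read's allele with a fixed
per-read error probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import variant_prob_matrix
from .panel import CloneFrequencies, CountsPanel, GenotypeMatrix

__all__ = ["SimulationTruth", "simulate", "inject_noise"]

#: Default Bernoulli success probability for tumor-clone genotype bits.
DEFAULT_GENOTYPE_P = 0.3
#: Default mean sequencing depth per locus.
DEFAULT_COVERAGE = 1000


@dataclass
class SimulationTruth:
    """A simulated panel together with its generating parameters."""

    panel: CountsPanel
    W_true: GenotypeMatrix
    P_true: CloneFrequencies
    params: dict


def simulate(
    M: int,
    S: int,
    C: int,
    mean_coverage: int = DEFAULT_COVERAGE,
    genotype_p: float = DEFAULT_GENOTYPE_P,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> SimulationTruth:
    """Draw one synthetic dataset of M loci × S subsections with C clones.

    Coverage: each subsection's column of ``N`` is
    ``Multinomial(M * mean_coverage, uniform over loci)``, so the column
    total is exactly ``M * mean_coverage``.  Genotypes: tumor-clone bits
    are iid ``Bernoulli(genotype_p)``; the normal clone is all zero.
    Frequencies: each column of ``P`` is a normalized vector of iid
    ``Uniform(0, 1)`` draws, then the first (normal-subsection) column is
    replaced by ``(1, 0, ..., 0)``.  Counts: ``X ~ Binomial(N, B)`` with
    ``B = W @ P / 2``; optional per-read flip noise at ``noise_rate``.

    Fully reproducible from ``seed``; the noise step uses an RNG stream
    derived from the same seed.
    """
    if min(M, S, C) < 1:
        raise ValueError("M, S and C must be positive")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = np.random.default_rng(seed)
    N = np.column_stack(
        [rng.multinomial(M * mean_coverage, np.full(M, 1.0 / M)) for _ in range(S)]
    )
    W = np.zeros((M, C), dtype=np.int8)
    if C > 1:
        W[:, 1:] = rng.binomial(1, genotype_p, size=(M, C - 1))
    P = rng.uniform(size=(C, S))
    P /= P.sum(axis=0, keepdims=True)
    P[:, 0] = 0.0
    P[0, 0] = 1.0
    B = (W @ P) / 2.0
    X = rng.binomial(N, B)
    panel = CountsPanel(
        X=X,
        N=N,
        loci=[f"L{i}" for i in range(M)],
        subsections=["normal"] + [f"T{j}" for j in range(1, S)],
    )
    if noise_rate > 0:
        panel = inject_noise(panel, noise_rate, seed=int(rng.integers(2**31)))
    return SimulationTruth(
        panel=panel,
        W_true=GenotypeMatrix(W),
        # delta_normal=0: the simulated normal subsection is exactly pure
        P_true=CloneFrequencies(P, delta_normal=0.0),
        params=dict(M=M, S=S, C=C, mean_coverage=mean_coverage,
                    genotype_p=genotype_p, noise_rate=noise_rate, seed=seed),
    )


def inject_noise(panel: CountsPanel, error_rate: float, seed: int = 0) -> CountsPanel:
    """Flip each read's allele call independently with ``error_rate``.

    Variant reads revert to normal and normal reads flip to variant, each
    with probability ``error_rate``:
    ``X' = X - Binomial(X, e) + Binomial(N - X, e)``.  Coverage is
    unchanged and ``0 <= X' <= N`` holds by construction.
    """
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if error_rate == 0:
        return panel
    rng = np.random.default_rng(seed)
    lost = rng.binomial(panel.X, error_rate)
    gained = rng.binomial(panel.N - panel.X, error_rate)
    return CountsPanel(
        X=panel.X - lost + gained,
        N=panel.N.copy(),
        loci=list(panel.loci),
        subsections=list(panel.subsections),
    )
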