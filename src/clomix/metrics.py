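"""Permutation-matched error metrics between true and estimated solutions.

Tumor-clone labels are arbitrary, so estimated solutions are compared to
the truth under the tumor-clone column permutation minimizing the genotype
error; the same permutation is then used for the frequency error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .panel import CloneFrequencies, GenotypeMatrix, PanelValidationError

__all__ = ["ErrorReport", "match_and_score", "match_genotypes"]

#: Exhaustive permutation search is used up to this many clones (total);
#: beyond it, a Hungarian assignment on the per-pair mismatch matrix gives
#: the same optimum because the cost is additive over matched columns.
EXHAUSTIVE_LIMIT = 9


@dataclass
class ErrorReport:
    """Genotype error, frequency error and the matching permutation.

    ``permutation[c]`` gives, for each estimated clone index ``c``, the
    matched true clone index; the normal clone is fixed (``permutation[0]
    == 0``).  ``genotype_error`` is the mean absolute genotype difference
    over tumor-clone entries; ``frequency_error`` the mean absolute
    frequency difference over all entries, both under that permutation.
    """

    genotype_error: float
    frequency_error: float
    permutation: tuple[int, ...]


def _best_tumor_permutation(W_true: np.ndarray, W_est: np.ndarray) -> tuple[tuple[int, ...], int]:
    """Minimize total genotype mismatch over tumor-clone permutations.

    Returns (perm over tumor indices 0..T-1 mapping est -> true, mismatch).
    """
    T = W_true.shape[1]
    # cost[e, t] = mismatches if estimated tumor clone e plays true clone t
    cost = np.array(
        [[int(np.abs(W_est[:, e] - W_true[:, t]).sum()) for t in range(T)]
         for e in range(T)]
    )
    if T + 1 <= EXHAUSTIVE_LIMIT:
        best, best_cost = None, None
        for perm in itertools.permutations(range(T)):
            c = sum(cost[e, perm[e]] for e in range(T))
            if best_cost is None or c < best_cost:
                best, best_cost = perm, c
        return tuple(best), int(best_cost)
    rows, cols = linear_sum_assignment(cost)
    perm = tuple(int(cols[np.argmax(rows == e)]) for e in range(T))
    return perm, int(cost[rows, cols].sum())


def match_genotypes(W_true: GenotypeMatrix, W_est: GenotypeMatrix) -> tuple[tuple[int, ...], int]:
    """Best tumor-clone matching and its total bit mismatch.

    The returned permutation is over full clone indices with the normal
    clone fixed at 0.
    """
    if W_true.W.shape != W_est.W.shape:
        raise PanelValidationError(
            f"genotype shapes differ: {W_true.W.shape} vs {W_est.W.shape}"
        )
    perm_t, mismatch = _best_tumor_permutation(W_true.W[:, 1:], W_est.W[:, 1:])
    return (0,) + tuple(p + 1 for p in perm_t), mismatch


def match_and_score(
    W_true: GenotypeMatrix,
    P_true: CloneFrequencies,
    W_est: GenotypeMatrix,
    P_est: CloneFrequencies,
) -> ErrorReport:
    """Compute permutation-matched genotype and frequency errors.

    The genotype error averages absolute genotype differences over the
    M×(C-1) tumor-clone entries under the mismatch-minimizing permutation;
    the frequency error averages absolute frequency differences over all
    C×S entries under that same permutation.
    """
    if P_true.P.shape != P_est.P.shape:
        raise PanelValidationError(
            f"frequency shapes differ: {P_true.P.shape} vs {P_est.P.shape}"
        )
    perm, mismatch = match_genotypes(W_true, W_est)
    M, C = W_true.W.shape
    eps_w = mismatch / (M * (C - 1))
    # reorder estimated rows so clone perm[c] aligns with true clone
    P_aligned = np.empty_like(P_est.P)
    for e, t in enumerate(perm):
        P_aligned[t] = P_est.P[e]
    eps_p = float(np.abs(P_true.P - P_aligned).mean())
    return ErrorReport(genotype_error=float(eps_w), frequency_error=eps_p,
                       permutation=perm)
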