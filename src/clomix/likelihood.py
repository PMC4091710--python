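"""Probability functions of the binomial clonal-mixture model.

The generative model: each clone ``c`` carries the variant at locus ``i``
with probability ``theta[c]`` (``Z[i,c] ~ Bernoulli(theta[c])``, with the
normal clone fixed to the all-zero genotype).  A sequenced read from
subsection ``j`` shows the variant allele at locus ``i`` with probability

    B[i,j] = (Z[i,:] @ P[:,j]) / 2

— the summed frequency of carrier clones, halved because carriers are
assumed heterozygous with copy number 1.  Variant read counts are then
binomial: ``X[i,j] ~ Binomial(N[i,j], B[i,j])``, independently across loci
and subsections given the parameters.

Conventions used throughout:

* Binomial coefficient terms are constant in the parameters.  They are
  INCLUDED in the log-likelihoods reported by this module (so values are
  comparable across software) and EXCLUDED inside the EM optimization
  (see :mod:`clomix.em`).
* Reported likelihoods are exact: a structurally impossible observation
  (``X > 0`` where ``B = 0``) yields ``-inf``, never a clipped value.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp, xlog1py, xlogy

from .panel import (
    CloneFrequencies,
    CountsPanel,
    GenotypeMatrix,
    MutationPrior,
    PanelValidationError,
)

__all__ = [
    "ENUMERATION_CAP",
    "variant_read_prob",
    "variant_prob_matrix",
    "enumerate_genotypes",
    "complete_loglik",
    "observed_loglik",
    "binom_logcoef",
]

#: Largest clone count for which the 2^(C-1) genotype vectors per locus are
#: enumerated.  4096 vectors per locus; clone counts in practice stay at or
#: below the number of subsections.
ENUMERATION_CAP = 12


class EnumerationCapError(ValueError):
    """Clone count too large for exhaustive genotype enumeration."""


def variant_read_prob(z, p_col) -> float:
    """Probability a read shows the variant allele, given genotype ``z``.

    Equals ``(sum_c z[c] * p_col[c]) / 2`` — each carrier clone contributes
    half its subsection frequency (heterozygous, copy number 1) — and hence
    lies in ``[0, 0.5]``.
    """
    z = np.asarray(z)
    if not np.isin(z, (0, 1)).all():
        raise PanelValidationError("genotype vector must be binary")
    if z[0] != 0:
        raise PanelValidationError("normal clone entry z[0] must be 0")
    p_col = np.asarray(p_col, dtype=float)
    return float(z @ p_col / 2.0)


def variant_prob_matrix(W: GenotypeMatrix | np.ndarray, P: CloneFrequencies | np.ndarray) -> np.ndarray:
    """M×S matrix of variant-read probabilities ``B = (W @ P) / 2``."""
    Wm = W.W if isinstance(W, GenotypeMatrix) else np.asarray(W)
    Pm = P.P if isinstance(P, CloneFrequencies) else np.asarray(P, dtype=float)
    return (Wm @ Pm) / 2.0


def enumerate_genotypes(C: int) -> np.ndarray:
    """All 2^(C-1) admissible genotype vectors as a (K, C) binary matrix.

    Column 0 (normal clone) is identically zero.  Row ``k`` encodes ``k``
    in binary with clone 1 as the least-significant bit, so row 0 is the
    all-zero genotype.
    """
    if C > ENUMERATION_CAP:
        raise EnumerationCapError(
            f"C={C} exceeds the enumeration cap of {ENUMERATION_CAP}; "
            "use fewer clones"
        )
    K = 2 ** (C - 1)
    ks = np.arange(K)
    Z = np.zeros((K, C), dtype=np.int8)
    for c in range(1, C):
        Z[:, c] = (ks >> (c - 1)) & 1
    return Z


def binom_logcoef(panel: CountsPanel) -> float:
    """Sum over all cells of ``log C(N[i,j], X[i,j])``."""
    N, X = panel.N, panel.X
    return float(np.sum(gammaln(N + 1) - gammaln(X + 1) - gammaln(N - X + 1)))


def _bernoulli_logmass(Z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Log Bernoulli mass of each row of binary ``Z`` under ``theta``.

    Only tumor clones (columns >= 1) contribute; the normal clone is
    deterministic.  ``xlogy`` conventions give exact ``-inf`` on
    impossible rows (e.g. a mutation under ``theta[c] = 0``).
    """
    t = theta[1:]
    Zt = Z[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (xlogy(Zt, t) + xlog1py(1 - Zt, -t)).sum(axis=1)


def _binom_logmass(X: np.ndarray, N: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Elementwise ``X log B + (N-X) log(1-B)`` with exact 0*log(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return xlogy(X, B) + xlog1py(N - X, -B)


def complete_loglik(
    panel: CountsPanel,
    W: GenotypeMatrix,
    P: CloneFrequencies,
    theta: MutationPrior,
    include_coef: bool = True,
) -> float:
    """Complete-data log-likelihood ``log p(X, Z=W | P, theta)``.

    The sum of the Bernoulli log-mass of the genotype matrix under the
    mutation prior and the binomial log-mass of the counts given the
    variant-read probabilities implied by ``(W, P)``.  Returns ``-inf``
    for observations that are impossible under the model (documented
    behavior, not an exception).
    """
    B = variant_prob_matrix(W, P)
    bern = float(_bernoulli_logmass(W.W, theta.theta).sum())
    binom = float(_binom_logmass(panel.X, panel.N, B).sum())
    total = bern + binom
    if include_coef and np.isfinite(total):
        total += binom_logcoef(panel)
    return total


def loglik_by_genotype(
    panel: CountsPanel, Z: np.ndarray, P: np.ndarray, clip: bool = True
) -> np.ndarray:
    """(M, K) matrix of per-locus binomial log-masses for each genotype row.

    Entry ``(i, k)`` is ``sum_j X[i,j] log B[k,j] + (N-X)[i,j] log(1-B[k,j])``
    with ``B[k,j] = Z[k,:] @ P[:,j] / 2`` (no binomial coefficients).  With
    ``clip=True`` probabilities are floored at a tiny constant so the result
    stays finite (suitable for the EM inner loop); with ``clip=False``
    impossible combinations are exactly ``-inf``.
    """
    B = (Z @ P) / 2.0
    if clip:
        logB = np.log(np.clip(B, 1e-300, None))
        log1mB = np.log1p(-np.clip(B, None, 1 - 1e-16))
        return panel.X @ logB.T + (panel.N - panel.X) @ log1mB.T
    out = np.empty((panel.n_loci, Z.shape[0]))
    for k in range(Z.shape[0]):
        out[:, k] = _binom_logmass(panel.X, panel.N, B[k][None, :]).sum(axis=1)
    return out


def observed_loglik(
    panel: CountsPanel,
    P: CloneFrequencies,
    theta: MutationPrior,
    include_coef: bool = True,
) -> float:
    """Observed-data log-likelihood, marginalized over genotypes.

    Per locus, sums ``Pr(z | theta) * prod_j Binom(X; N, B(z))`` over all
    2^(C-1) admissible genotype vectors; accumulated with log-sum-exp.
    """
    Z = enumerate_genotypes(P.n_clones)
    prior = _bernoulli_logmass(Z, theta.theta)          # (K,)
    ll = loglik_by_genotype(panel, Z, P.P, clip=False)  # (M, K)
    with np.errstate(invalid="ignore"):
        per_locus = logsumexp(prior[None, :] + ll, axis=1)
    total = float(per_locus.sum())
    if include_coef and np.isfinite(total):
        total += binom_logcoef(panel)
    return total
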