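"""EM fitting of clone genotypes and frequencies.

The E step enumerates all 2^(C-1) admissible genotype vectors per locus and
applies Bayes' theorem in log space.  The M step has a closed-form update
for the mutation prior (the mean posterior marginal per clone) and a
box-constrained L-BFGS-B update with analytic gradient for the clone
frequencies.  Convergence is declared when the relative change of the
expected complete-data log-likelihood Q* (the quantity maximized in the
last M step) falls below a threshold.

Simplex handling in the frequency update: only the tumor-clone entries
``P[1:, j]`` are free box-constrained variables; the normal-clone entry is
defined implicitly as ``P[0, j] = 1 - sum_c P[c, j]``.  Because the normal
clone never carries a variant, the objective depends on the tumor entries
only; a quadratic penalty keeps each column's tumor mass below
``1 - delta_normal`` so the implicit normal fraction respects the
contamination floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, xlog1py, xlogy

from . import likelihood as lk
from .panel import (
    CloneFrequencies,
    CountsPanel,
    EMResult,
    GenotypeMatrix,
    MutationPrior,
)

__all__ = ["EMConfig", "PosteriorTable", "e_step", "m_step_theta", "m_step_P",
           "run_em", "fit_many"]

logger = logging.getLogger(__name__)

_PENALTY = 1e8  # weight of the quadratic over-mass penalty in the P update


class CloneCountError(ValueError):
    """C outside the admissible range for this panel."""


@dataclass(frozen=True)
class EMConfig:
    """Tuning knobs of the EM driver.

    epsilon is the relative Q* improvement below which iteration stops;
    restart r of a multi-restart fit uses seed ``(seed + r) mod 2^31``.
    """

    epsilon: float = 1e-3
    max_iter: int = 1000
    n_restarts: int = 10
    seed: int = 0
    delta_normal: float = 1e-3
    optimizer_maxfun: int = 500
    optimizer_pgtol: float = 1e-8
    enumeration_cap: int = lk.ENUMERATION_CAP
    call_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class PosteriorTable:
    """E-step output: per-locus posterior over genotype vectors.

    ``q[i, k]`` is the posterior probability of genotype vector
    ``z_enum[k]`` at locus ``i``; ``marginals[i, c]`` the per-clone
    marginal ``P(Z[i,c] = 1 | X, P, theta)``.  ``bin_loglik`` caches the
    (M, K) binomial log-mass matrix (no coefficients) used to assemble Q*.
    """

    q: np.ndarray
    z_enum: np.ndarray
    marginals: np.ndarray
    bin_loglik: np.ndarray
    log_evidence: np.ndarray  # per-locus log normalizer (no coefficients)


class DegeneratePosteriorError(ValueError):
    """A locus admits no genotype with positive posterior mass."""


def e_step(panel: CountsPanel, P: CloneFrequencies, theta: MutationPrior,
           strict: bool = True) -> PosteriorTable:
    """Posterior over genotype vectors per locus via Bayes' theorem.

    ``q_i(z) ∝ Pr(z | theta) * prod_j Binom(X[i,j]; N[i,j], B(z, P[:,j]))``,
    computed and normalized in log space.

    With ``strict=True`` a structurally impossible locus (``X > 0`` where
    every admissible genotype yields ``B = 0``) raises a per-locus error.
    The EM driver passes ``strict=False``: parameters can transiently sit
    exactly on a zero bound (e.g. no tumor fraction in the normal
    subsection while sequencing noise produced a few variant reads), and
    there the clipped log-mass still orders the genotypes correctly.
    """
    Z = lk.enumerate_genotypes(P.n_clones)
    prior = lk._bernoulli_logmass(Z, theta.theta)         # (K,)
    ll = lk.loglik_by_genotype(panel, Z, P.P, clip=True)  # (M, K)
    logpost = prior[None, :] + ll
    if strict:
        # clipping keeps ll finite; restore exact impossibility
        B = (Z @ P.P) / 2.0
        impossible = (panel.X > 0).astype(np.int8) @ (B.T == 0).astype(np.int8) > 0
        logpost = np.where(impossible, -np.inf, logpost)
    norm = logsumexp(logpost, axis=1)
    bad = ~np.isfinite(norm)
    if bad.any():
        i = int(np.argmax(bad))
        raise DegeneratePosteriorError(
            f"locus '{panel.loci[i]}' has zero posterior mass under every "
            "admissible genotype"
        )
    q = np.exp(logpost - norm[:, None])
    marginals = np.clip(q @ Z, 0.0, 1.0)
    marginals[:, 0] = 0.0
    return PosteriorTable(q=q, z_enum=Z, marginals=marginals,
                          bin_loglik=ll, log_evidence=norm)


def m_step_theta(post: PosteriorTable) -> MutationPrior:
    """Closed-form prior update: mean posterior marginal per tumor clone."""
    theta = np.clip(post.marginals.mean(axis=0), 0.0, 1.0)
    theta[0] = 0.0
    return MutationPrior(theta)


def _q1_parts(panel: CountsPanel, post: PosteriorTable):
    # collapse loci: A[k,j] = sum_i q[i,k] X[i,j]; D likewise for N-X
    A = post.q.T @ panel.X
    D = post.q.T @ (panel.N - panel.X)
    Zt = post.z_enum[:, 1:].astype(float)
    return A, D, Zt


def q1_binomial(panel: CountsPanel, post: PosteriorTable, P: np.ndarray) -> float:
    """Expected binomial term Q1(P) of the complete-data log-likelihood."""
    A, D, Zt = _q1_parts(panel, post)
    B = (Zt @ P[1:]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        val = xlogy(A, B) + xlog1py(D, -B)
    return float(val.sum())


def _q1_objective(A, D, Zt, delta_normal):
    """Return (negated objective, gradient) closure over flat tumor entries."""
    K, T = Zt.shape
    S = A.shape[1]

    def fun(x):
        Pt = x.reshape(T, S)
        B = (Zt @ Pt) / 2.0
        Bc = np.clip(B, 1e-300, 1 - 1e-12)
        val = float((xlogy(A, Bc) + xlog1py(D, -Bc)).sum())
        # gradient of Q1 wrt tumor entries, via dB/dP[c,j] = Z[k,c]/2
        inner = A / Bc - D / (1.0 - Bc)          # (K, S)
        grad = (Zt.T @ inner) / 2.0              # (T, S)
        # soft penalty keeping each column's tumor mass <= 1 - delta
        over = np.clip(Pt.sum(axis=0) - (1.0 - delta_normal), 0.0, None)
        val -= _PENALTY * float((over ** 2).sum())
        grad -= 2.0 * _PENALTY * over[None, :]
        return -val, -grad.ravel()

    return fun


def m_step_P(
    panel: CountsPanel,
    post: PosteriorTable,
    P_current: CloneFrequencies,
    config: EMConfig,
    x0: np.ndarray | None = None,
) -> tuple[CloneFrequencies, bool]:
    """Frequency update: maximize Q1 over box-constrained tumor entries.

    Returns the new frequencies and a flag that is True when the optimizer
    failed to improve on ``P_current`` and the current value was kept
    (preserving EM monotonicity).
    """
    A, D, Zt = _q1_parts(panel, post)
    delta = config.delta_normal
    T, S = Zt.shape[1], A.shape[1]
    fun = _q1_objective(A, D, Zt, delta)
    if x0 is None:
        x0 = P_current.P[1:].ravel().copy()
    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, 1.0 - delta)] * (T * S),
        options={"maxfun": config.optimizer_maxfun, "gtol": config.optimizer_pgtol,
                 "ftol": 1e-12},
    )
    Pt = res.x.reshape(T, S)
    # project any residual over-mass back inside the simplex
    mass = Pt.sum(axis=0)
    over = mass > 1.0 - delta
    if over.any():
        Pt[:, over] *= (1.0 - delta) / mass[over]
        mass = Pt.sum(axis=0)
    P_new = np.vstack([1.0 - mass, Pt])
    new = CloneFrequencies(P_new, delta_normal=delta)
    q1_new = q1_binomial(panel, post, new.P)
    q1_old = q1_binomial(panel, post, P_current.P)
    if q1_new < q1_old - 1e-8 * max(1.0, abs(q1_old)):
        logger.debug("P update did not improve Q1; keeping current P")
        return P_current, True
    return new, False


def _q_star(panel, post, P, theta, logcoef):
    """Expected complete-data log-likelihood at (P, theta) under posterior q.

    The Bernoulli part is linear in the binary genotype entries, so the
    per-clone marginals suffice; the binomial part contracts the posterior
    table against the per-genotype log-mass matrix.
    """
    m = post.marginals[:, 1:]
    t = theta.theta[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        bern = xlogy(m, t) + xlog1py(1 - m, -t)
    q1 = q1_binomial(panel, post, P.P)
    return float(bern.sum()) + q1 + logcoef


def _init_parameters(C, S, rng, delta):
    P = rng.uniform(size=(C, S))
    P /= P.sum(axis=0, keepdims=True)
    low = P[0] < delta
    if low.any():
        # pin the normal fraction at the floor, rescale the tumor mass
        P[1:, low] *= (1.0 - delta) / P[1:, low].sum(axis=0, keepdims=True)
        P[0, low] = delta
    theta = rng.uniform(size=C)
    theta[0] = 0.0
    return CloneFrequencies(P, delta_normal=delta), MutationPrior(theta)


def run_em(panel: CountsPanel, C: int, config: EMConfig | None = None,
           allow_extra_clones: bool = False) -> EMResult:
    """Fit a C-clone model from one seeded random initialization.

    Alternates the E step, the closed-form theta update and the L-BFGS-B
    frequency update until the relative change of Q* drops below
    ``config.epsilon`` or ``config.max_iter`` is reached.  Genotypes are
    called by thresholding marginals at 0.5 (ties round to 1).
    """
    config = config or EMConfig()
    S = panel.n_subsections
    if C < 2:
        raise CloneCountError("need at least 2 clones (normal + 1 tumor)")
    if C > S and not allow_extra_clones:
        raise CloneCountError(
            f"C={C} exceeds the number of subsections S={S}; the model is "
            "under-constrained (pass allow_extra_clones=True to override)"
        )
    if C > config.enumeration_cap:
        raise lk.EnumerationCapError(
            f"C={C} exceeds the enumeration cap {config.enumeration_cap}"
        )
    rng = np.random.default_rng(config.seed)
    P, theta = _init_parameters(C, S, rng, config.delta_normal)
    logcoef = lk.binom_logcoef(panel)

    obs_trace: list[float] = []  # observed loglik, free from the E step
    q_trace: list[float] = []    # Q* after each M step (stopping rule, BIC)
    fallbacks = 0
    converged = False
    post = None
    for it in range(config.max_iter):
        post = e_step(panel, P, theta, strict=False)
        obs_trace.append(float(post.log_evidence.sum()) + logcoef)
        theta = m_step_theta(post)
        P, failed = m_step_P(panel, post, P, config)
        fallbacks += int(failed)
        q = _q_star(panel, post, P, theta, logcoef)
        q_trace.append(q)
        if it > 0:
            prev = q_trace[-2]
            if abs(q - prev) < config.epsilon * abs(q):
                converged = True
                break
    # refresh the posterior at the final parameters for calling genotypes
    post = e_step(panel, P, theta, strict=False)
    marginals = post.marginals
    W = (marginals >= config.call_threshold).astype(np.int8)
    W[:, 0] = 0
    obs = lk.observed_loglik(panel, P, theta)
    obs_trace.append(float(post.log_evidence.sum()) + logcoef)
    return EMResult(
        P=P,
        theta=theta,
        marginals=marginals,
        W_called=GenotypeMatrix(W),
        loglik_trace=np.asarray(obs_trace),
        q_star_trace=np.asarray(q_trace),
        observed_loglik=obs,
        converged=converged,
        n_iter=len(q_trace),
        seed=config.seed,
        optimizer_fallbacks=fallbacks,
    )


def fit_many(panel: CountsPanel, C: int, config: EMConfig | None = None,
             allow_extra_clones: bool = False) -> tuple[EMResult, list[float]]:
    """Run EM from ``config.n_restarts`` seeded initializations.

    Restart r uses seed ``(config.seed + r) mod 2^31``.  Returns the
    restart with the highest final Q* together with every restart's final
    Q* (for restart-sufficiency analysis).
    """
    config = config or EMConfig()
    best: EMResult | None = None
    finals: list[float] = []
    for r in range(config.n_restarts):
        cfg = replace(config, seed=(config.seed + r) % 2**31)
        res = run_em(panel, C, cfg, allow_extra_clones=allow_extra_clones)
        finals.append(res.Q_star)
        logger.info("restart %d: Q*=%.6f", r, res.Q_star)
        if best is None or res.Q_star > best.Q_star:
            best = res
    assert best is not None
    return best, finals
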