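"""Clonal phylogeny construction, validity testing and repair.

A genotype matrix admits a mutation-unique clonal tree (a perfect
phylogeny rooted at the normal clone) exactly when the carrier sets of
every pair of mutations are nested or disjoint.  When a matrix fails this
test, "nearby" candidates — matrices differing in exactly one bit among
the distinct row patterns — are enumerated, filtered for validity, and
rescored under the model with the genotype held fixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from . import likelihood as lk
from .em import EMConfig, fit_many, m_step_P, PosteriorTable
from .metrics import match_genotypes
from .panel import (
    CloneFrequencies,
    CountsPanel,
    GenotypeMatrix,
    MutationPrior,
    PanelValidationError,
)

__all__ = [
    "PhyloTree",
    "RepairCandidate",
    "GenotypeScore",
    "is_valid_phylogeny",
    "build_tree",
    "nearby_variants",
    "score_genotype",
    "repair_genotype",
    "leave_one_out",
]


@dataclass
class PhyloTree:
    """Rooted clone tree with mutation sets on edges.

    Node 0 is the root and holds the normal clone (plus any tumor clone
    whose genotype is empty).  Every other node corresponds to one
    distinct mutation carrier set; the edge into it carries exactly the
    mutations with that carrier set, so every mutation appears on exactly
    one edge.  A node carries the clones whose genotype equals the union
    of edge mutations on its root path; nodes without clones are implied
    (unobserved) ancestors, e.g. a trunk shared by two observed clones.
    """

    parent: dict[int, int | None]
    edge_mutations: dict[int, frozenset[int]]
    clones: dict[int, tuple[int, ...]]
    clone_labels: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    @property
    def root(self) -> int:
        return next(n for n, p in self.parent.items() if p is None)

    def genotype_of(self, node: int) -> frozenset[int]:
        """Union of edge mutations on the path from the root to ``node``."""
        muts: set[int] = set()
        cur: int | None = node
        while cur is not None:
            muts |= self.edge_mutations.get(cur, frozenset())
            cur = self.parent[cur]
        return frozenset(muts)

    def carrier_clones(self, node: int) -> frozenset[int]:
        """Clones at or below ``node`` (the carrier set of its edge)."""
        kids = [n for n, p in self.parent.items() if p == node]
        out = set(self.clones.get(node, ()))
        for k in kids:
            out |= self.carrier_clones(k)
        return frozenset(out)

    def to_genotype_matrix(self, n_loci: int, n_clones: int | None = None) -> GenotypeMatrix:
        """Read clone genotypes back off the tree (round-trip inverse)."""
        C = n_clones or (max(c for cs in self.clones.values() for c in cs) + 1)
        W = np.zeros((n_loci, C), dtype=np.int8)
        for node, cs in self.clones.items():
            for i in self.genotype_of(node):
                for c in cs:
                    W[i, c] = 1
        W[:, 0] = 0
        return GenotypeMatrix(W)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes:
            g.add_node(node, clones=self.clones.get(node, ()))
        for node, par in self.parent.items():
            if par is not None:
                g.add_edge(par, node, mutations=sorted(self.edge_mutations[node]))
        return g

    def _name(self, node: int) -> str:
        cs = self.clones.get(node, ())
        if not cs:
            return f"anc{node}"
        return "+".join(
            self.clone_labels[c] if self.clone_labels else f"C{c}" for c in cs
        )

    def to_newick(self, loci: list[str] | None = None) -> str:
        """Newick string with clone labels; edge mutations in comments."""
        children: dict[int, list[int]] = {n: [] for n in self.nodes}
        for node, par in self.parent.items():
            if par is not None:
                children[par].append(node)

        def muts(node):
            ms = sorted(self.edge_mutations.get(node, frozenset()))
            if not ms:
                return ""
            txt = ",".join(loci[i] if loci else str(i) for i in ms)
            return f"[&mutations={txt}]"

        def rec(node):
            kids = sorted(children[node])
            inner = ",".join(rec(k) for k in kids)
            base = f"({inner}){self._name(node)}" if kids else self._name(node)
            return base + muts(node)

        return rec(self.root) + ";"

    def topology(self) -> frozenset:
        """Hashable canonical form: each edge as (mutation set, carrier set).

        Two trees over the same clones are identical exactly when these
        pairs coincide, independent of internal node numbering.
        """
        return frozenset(
            (self.edge_mutations[n], self.carrier_clones(n))
            for n in self.nodes
            if self.parent[n] is not None
        )


@dataclass
class RepairCandidate:
    """One single-bit repair of a genotype matrix.

    The flip is applied uniformly to every locus sharing the flipped
    distinct row pattern.
    """

    pattern: tuple[int, ...]      # the distinct tumor-clone row pattern flipped
    clone: int                    # full clone index of the flipped bit
    loci: tuple[int, ...]         # locus indices sharing the pattern
    W: GenotypeMatrix
    score: "GenotypeScore | None" = None


@dataclass
class GenotypeScore:
    """Likelihood of a panel under a fixed genotype matrix.

    Both conventions of the complete-data log-likelihood are reported
    because printed values in the literature do not always state whether
    Bernoulli prior terms and binomial coefficients are included; rankings
    agree across conventions for a fixed clone count.
    """

    complete_loglik: float        # Bernoulli prior + binomial mass + coefficients
    binomial_loglik: float        # binomial mass only, no coefficients
    observed_loglik: float
    P: CloneFrequencies
    theta: MutationPrior


def _carrier_conflict(W: np.ndarray) -> tuple[int, int] | None:
    """Find two loci whose carrier sets overlap without nesting."""
    patterns: dict[tuple[int, ...], int] = {}
    for i in range(W.shape[0]):
        pat = tuple(int(v) for v in W[i])
        patterns.setdefault(pat, i)
    reps = list(patterns.items())
    for (pa, ia), (pb, ib) in itertools.combinations(reps, 2):
        a = np.asarray(pa, dtype=bool)
        b = np.asarray(pb, dtype=bool)
        both = (a & b).any()
        if both and (a & ~b).any() and (~a & b).any():
            return (ia, ib)
    return None


def is_valid_phylogeny(W: GenotypeMatrix) -> tuple[bool, tuple[int, int] | None]:
    """Test whether ``W`` admits a mutation-unique clonal tree.

    True iff every pair of mutations has nested or disjoint carrier-clone
    sets (the classic two-state perfect-phylogeny condition with the
    all-zero normal clone as the ancestral state).  On failure, returns a
    witness pair of locus indices with incompatible carrier sets.
    """
    conflict = _carrier_conflict(W.W)
    return (conflict is None), conflict


def build_tree(W: GenotypeMatrix) -> PhyloTree:
    """Construct the unique mutation-unique clone tree of a valid matrix.

    Distinct mutation carrier sets form a laminar family; each becomes one
    tree edge carrying exactly the mutations with that carrier set, nested
    under the smallest strictly containing set (the root if none).  Each
    clone attaches below the smallest carrier set containing it, so its
    genotype is the union of edge mutations on its root path.  Carrier
    sets that are no clone's minimal set yield implied (unlabeled)
    ancestor nodes, e.g. a shared trunk.
    """
    ok, witness = is_valid_phylogeny(W)
    if not ok:
        i, j = witness
        raise PanelValidationError(
            f"no mutation-unique tree exists: loci {i} and {j} have "
            "overlapping, non-nested carrier clone sets"
        )
    C = W.n_clones
    # group loci by carrier set (the clones sharing that mutation pattern)
    by_carriers: dict[frozenset[int], set[int]] = {}
    for i in range(W.W.shape[0]):
        carriers = frozenset(np.flatnonzero(W.W[i]).tolist())
        if carriers:
            by_carriers.setdefault(carriers, set()).add(i)
    sets = sorted(by_carriers, key=len, reverse=True)
    node_of: dict[frozenset[int], int] = {}
    parent: dict[int, int | None] = {0: None}
    edges: dict[int, frozenset[int]] = {0: frozenset()}
    for idx, s in enumerate(sets, start=1):
        supersets = [t for t in sets if s < t]
        par = node_of[min(supersets, key=len)] if supersets else 0
        node_of[s] = idx
        parent[idx] = par
        edges[idx] = frozenset(by_carriers[s])
    clones: dict[int, list[int]] = {n: [] for n in parent}
    for c in range(C):
        containing = [s for s in sets if c in s]
        node = node_of[min(containing, key=len)] if containing else 0
        clones[node].append(c)
    return PhyloTree(
        parent=parent,
        edge_mutations=edges,
        clones={n: tuple(cs) for n, cs in clones.items()},
        clone_labels=list(W.clone_labels),
    )


def nearby_variants(W: GenotypeMatrix) -> list[RepairCandidate]:
    """Enumerate valid one-bit repairs over distinct row patterns.

    Every distinct tumor-clone row pattern × tumor clone combination is
    flipped (simultaneously for all loci sharing the pattern); candidates
    failing the validity test are dropped.  The unmodified matrix is never
    part of the result.
    """
    M, C = W.W.shape
    groups: dict[tuple[int, ...], list[int]] = {}
    for i in range(M):
        groups.setdefault(tuple(int(v) for v in W.W[i]), []).append(i)
    out = []
    for pat, loci in groups.items():
        for c in range(1, C):
            W2 = W.W.copy()
            W2[loci, c] = 1 - W2[loci, c]
            cand = GenotypeMatrix(W2, clone_labels=list(W.clone_labels))
            ok, _ = is_valid_phylogeny(cand)
            if ok:
                out.append(RepairCandidate(pattern=pat, clone=c,
                                           loci=tuple(loci), W=cand))
    return out


def _fixed_w_posterior(panel: CountsPanel, W: GenotypeMatrix) -> PosteriorTable:
    """Degenerate posterior placing all mass on each locus's row of W."""
    C = W.n_clones
    Z = lk.enumerate_genotypes(C)
    # index of each row of W in the enumeration (clone 1 = least significant bit)
    powers = 2 ** np.arange(C - 1)
    idx = (W.W[:, 1:] @ powers).astype(int)
    q = np.zeros((panel.n_loci, Z.shape[0]))
    q[np.arange(panel.n_loci), idx] = 1.0
    marg = W.W.astype(float)
    return PosteriorTable(q=q, z_enum=Z, marginals=marg,
                          bin_loglik=np.zeros_like(q), log_evidence=np.zeros(panel.n_loci))


def score_genotype(
    panel: CountsPanel,
    W_fixed: GenotypeMatrix,
    config: EMConfig | None = None,
    n_restarts: int = 200,
) -> GenotypeScore:
    """Maximize the model likelihood over (P, theta) with W held fixed.

    The E-step posterior is pinned on the rows of ``W_fixed``, so theta has
    the closed form ``mean(W[:, c])`` and the frequency update reduces to a
    single box-constrained optimization, restarted from ``n_restarts``
    random initializations (a much easier problem than the full EM).
    """
    config = config or EMConfig()
    C = W_fixed.n_clones
    theta_v = W_fixed.W.mean(axis=0)
    theta_v[0] = 0.0
    theta = MutationPrior(theta_v)
    post = _fixed_w_posterior(panel, W_fixed)
    rng = np.random.default_rng(config.seed)
    best_P, best_q1 = None, -np.inf
    from .em import q1_binomial

    for _ in range(n_restarts):
        P0 = rng.uniform(size=(C, panel.n_subsections))
        P0 /= P0.sum(axis=0, keepdims=True)
        low = P0[0] < config.delta_normal
        if low.any():
            P0[1:, low] *= (1.0 - config.delta_normal) / P0[1:, low].sum(axis=0, keepdims=True)
            P0[0, low] = config.delta_normal
        start = CloneFrequencies(P0, delta_normal=config.delta_normal)
        P1, _ = m_step_P(panel, post, start, config)
        q1 = q1_binomial(panel, post, P1.P)
        if q1 > best_q1:
            best_P, best_q1 = P1, q1
    assert best_P is not None
    complete = lk.complete_loglik(panel, W_fixed, best_P, theta)
    observed = lk.observed_loglik(panel, best_P, theta)
    return GenotypeScore(
        complete_loglik=complete,
        binomial_loglik=best_q1,
        observed_loglik=observed,
        P=best_P,
        theta=theta,
    )


def repair_genotype(
    panel: CountsPanel,
    W: GenotypeMatrix,
    config: EMConfig | None = None,
    n_restarts: int = 200,
) -> tuple[GenotypeMatrix, PhyloTree, list[RepairCandidate]]:
    """Return a tree-consistent genotype for ``W``, repairing if needed.

    If ``W`` is already valid its own tree is returned with no candidates.
    Otherwise every valid one-bit neighbor is scored with the genotype
    held fixed and the highest-likelihood candidate is adopted.
    """
    ok, _ = is_valid_phylogeny(W)
    if ok:
        return W, build_tree(W), []
    cands = nearby_variants(W)
    if not cands:
        raise PanelValidationError(
            "genotype matrix is invalid and has no valid one-bit repair"
        )
    for cand in cands:
        cand.score = score_genotype(panel, cand.W, config, n_restarts=n_restarts)
    best = max(cands, key=lambda c: c.score.complete_loglik)
    return best.W, build_tree(best.W), cands


@dataclass
class LeaveOneOutReport:
    """Stability of the called genotype under held-out tumor subsections."""

    held_out: list[str]
    bit_differences: list[int]     # Hamming distance to the full-data genotype
    same_tree: list[bool]          # repaired tree identical to full-data tree
    full_genotype: GenotypeMatrix
    full_tree: PhyloTree


def leave_one_out(
    panel: CountsPanel,
    C: int,
    config: EMConfig | None = None,
    repair_restarts: int = 50,
) -> LeaveOneOutReport:
    """Refit with each tumor subsection held out and compare genotypes.

    The matched normal is never held out.  Each held-out fit's called
    genotype is permutation-matched to the full-data genotype, its Hamming
    distance recorded, and its repaired tree compared to the full-data
    repaired tree.
    """
    if panel.n_subsections < 3:
        raise PanelValidationError("leave-one-out needs at least 3 subsections")
    config = config or EMConfig()
    full, _ = fit_many(panel, C, config)
    W_full = full.W_called
    _, full_tree, _ = repair_genotype(panel, W_full, config, n_restarts=repair_restarts)
    full_topo = full_tree.topology()
    held, bits, same = [], [], []
    for label in panel.subsections[1:]:
        sub = panel.drop_subsection(label)
        res, _ = fit_many(sub, C, config)
        perm, mismatch = match_genotypes(W_full, res.W_called)
        # reorder estimated columns to the full-data labeling
        W_re = np.empty_like(res.W_called.W)
        for e, t in enumerate(perm):
            W_re[:, t] = res.W_called.W[:, e]
        Wm = GenotypeMatrix(W_re)
        _, tree, _ = repair_genotype(sub, Wm, config, n_restarts=repair_restarts)
        held.append(label)
        bits.append(int(mismatch))
        same.append(tree.topology() == full_topo)
    return LeaveOneOutReport(
        held_out=held,
        bit_differences=bits,
        same_tree=same,
        full_genotype=W_full,
        full_tree=full_tree,
    )
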