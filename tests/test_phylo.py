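import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clomix import phylo
from clomix.em import EMConfig
from clomix.panel import GenotypeMatrix, PanelValidationError
from clomix.simulate import simulate


def published_c3_structure():
    """Two trunk mutations shared by both tumor clones, nine private to the
    first, six private to the second (17 loci, 3 clones)."""
    W = np.zeros((17, 3), dtype=int)
    W[:2, 1] = 1
    W[:2, 2] = 1
    W[2:11, 1] = 1
    W[11:, 2] = 1
    return GenotypeMatrix(W)


def random_tree_genotype(rng, C=None, M=None):
    """Paint random mutations on edges of a random clone tree."""
    C = C or int(rng.integers(2, 6))
    M = M or int(rng.integers(3, 15))
    parent = [None] + [int(rng.integers(0, c)) for c in range(1, C)]
    children = {c: [d for d in range(C) if parent[d] == c] for c in range(C)}

    def subtree(c):
        out = {c}
        for d in children[c]:
            out |= subtree(d)
        return out

    W = np.zeros((M, C), dtype=int)
    for i in range(M):
        c = int(rng.integers(1, C))
        W[i, list(subtree(c))] = 1
    W[:, 0] = 0
    return GenotypeMatrix(W)


def test_trunk_structure_is_valid_with_implied_ancestor():
    W = published_c3_structure()
    ok, witness = phylo.is_valid_phylogeny(W)
    assert ok and witness is None
    tree = phylo.build_tree(W)
    # trunk mutations sit on a single edge above an implied ancestor
    topo = dict((tuple(sorted(c)), tuple(sorted(m))) for m, c in tree.topology())
    assert topo[(1, 2)] == (0, 1)
    assert topo[(1,)] == tuple(range(2, 11))
    assert topo[(2,)] == tuple(range(11, 17))


def test_overlapping_non_nested_carriers_invalid():
    W = np.zeros((2, 4), dtype=int)
    W[0, [1, 2]] = 1
    W[1, [2, 3]] = 1
    ok, witness = phylo.is_valid_phylogeny(GenotypeMatrix(W))
    assert not ok
    assert sorted(witness) == [0, 1]


def test_build_tree_rejects_invalid():
    W = np.zeros((2, 4), dtype=int)
    W[0, [1, 2]] = 1
    W[1, [2, 3]] = 1
    with pytest.raises(PanelValidationError, match="non-nested"):
        phylo.build_tree(GenotypeMatrix(W))


def test_tree_genotype_round_trip_on_random_valid_instances():
    rng = np.random.default_rng(12)
    for _ in range(100):
        W = random_tree_genotype(rng)
        ok, _ = phylo.is_valid_phylogeny(W)
        assert ok
        tree = phylo.build_tree(W)
        back = tree.to_genotype_matrix(W.W.shape[0], W.n_clones)
        assert np.array_equal(back.W, W.W)
        # rebuilding from the read-off genotypes is the identity
        assert phylo.build_tree(back).topology() == tree.topology()


def test_all_zero_genotype_collapses_to_root():
    tree = phylo.build_tree(GenotypeMatrix(np.zeros((5, 3), dtype=int)))
    assert tree.nodes == [0]
    assert tree.clones[0] == (0, 1, 2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_validity_invariant_to_permutations(seed):
    rng = np.random.default_rng(seed)
    M, C = 8, 4
    W = np.zeros((M, C), dtype=int)
    W[:, 1:] = rng.integers(0, 2, size=(M, C - 1))
    Wm = GenotypeMatrix(W)
    ok, _ = phylo.is_valid_phylogeny(Wm)
    perm = [0, *rng.permutation(range(1, C))]
    rows = rng.permutation(M)
    ok2, _ = phylo.is_valid_phylogeny(GenotypeMatrix(W[np.ix_(rows, perm)]))
    assert ok == ok2


def test_nearby_variants_match_exhaustive_flip_search():
    rng = np.random.default_rng(7)
    for _ in range(10):
        M, C = 10, 4
        W = np.zeros((M, C), dtype=int)
        W[:, 1:] = rng.integers(0, 2, size=(M, C - 1))
        Wm = GenotypeMatrix(W)
        cands = phylo.nearby_variants(Wm)
        groups = {}
        for i in range(M):
            groups.setdefault(tuple(W[i]), []).append(i)
        expected = 0
        for pat, loci in groups.items():
            for c in range(1, C):
                W2 = W.copy()
                W2[loci, c] = 1 - W2[loci, c]
                ok, _ = phylo.is_valid_phylogeny(GenotypeMatrix(W2))
                expected += ok
        assert len(cands) == expected
        # each candidate differs from W in exactly one bit among the
        # distinct row patterns and is itself valid
        for cand in cands:
            flipped = np.argwhere(cand.W.W != W)
            assert {tuple(W[i]) for i, _ in flipped} == {cand.pattern}
            assert len({c for _, c in flipped}) == 1
            assert phylo.is_valid_phylogeny(cand.W)[0]


def test_random_matrices_rarely_valid():
    # with >=6 distinct patterns and C=4, validity is rare by chance
    rng = np.random.default_rng(3)
    n_valid = n_total = 0
    while n_total < 2000:
        W = np.zeros((8, 4), dtype=int)
        W[:, 1:] = rng.integers(0, 2, size=(8, 3))
        if len({tuple(r) for r in W}) < 6:
            continue
        n_total += 1
        n_valid += phylo.is_valid_phylogeny(GenotypeMatrix(W))[0]
    # rarity is a sanity check, not a sharp threshold: the chance shrinks
    # quickly with the number of distinct patterns
    assert n_valid / n_total < 0.3


def test_score_prefers_true_genotype():
    truth = simulate(M=15, S=4, C=3, seed=3)
    cfg = EMConfig(seed=0)
    sc_true = phylo.score_genotype(truth.panel, truth.W_true, cfg, n_restarts=20)
    rng = np.random.default_rng(1)
    for _ in range(3):
        Wc = truth.W_true.W.copy()
        i, c = rng.integers(truth.panel.n_loci), rng.integers(1, 3)
        Wc[i, c] = 1 - Wc[i, c]
        sc_bad = phylo.score_genotype(
            truth.panel, GenotypeMatrix(Wc), cfg, n_restarts=20
        )
        assert sc_true.complete_loglik >= sc_bad.complete_loglik


def test_score_invariant_to_clone_permutation():
    truth = simulate(M=10, S=4, C=3, seed=5)
    cfg = EMConfig(seed=0)
    a = phylo.score_genotype(truth.panel, truth.W_true, cfg, n_restarts=30)
    swapped = GenotypeMatrix(truth.W_true.W[:, [0, 2, 1]])
    b = phylo.score_genotype(truth.panel, swapped, cfg, n_restarts=30)
    assert a.complete_loglik == pytest.approx(b.complete_loglik, abs=1e-3)


def test_leave_one_out_counts_and_stability():
    truth = simulate(M=25, S=6, C=3, mean_coverage=1000, seed=13)
    rep = phylo.leave_one_out(
        truth.panel, 3, EMConfig(seed=0, n_restarts=5), repair_restarts=10
    )
    assert rep.held_out == truth.panel.subsections[1:]  # normal never held out
    assert len(rep.bit_differences) == 5
    # strongly separated simulated clones: every held-out fit recovers the tree
    assert all(rep.same_tree)
    assert all(b == 0 for b in rep.bit_differences)


def test_leave_one_out_requires_three_subsections():
    truth = simulate(M=5, S=2, C=2, seed=0)
    with pytest.raises(PanelValidationError):
        phylo.leave_one_out(truth.panel, 2, EMConfig(seed=0, n_restarts=1))
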