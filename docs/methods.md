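# Methods

## Generative model

For M somatic loci across S subsections of one tumor (subsection 1 =
matched normal), with C clones (clone 1 = normal, genotype fixed to zero):

- `Z[i,c] ~ Bernoulli(theta[c])` independently for tumor clones `c >= 2`;
  `theta[1] = 0`.
- `B[i,j] = (Z[i,·] · P[·,j]) / 2` — the variant-read probability. The
  factor 1/2 encodes the assumption that a carrier clone is heterozygous
  with copy number 1 at every tracked locus, so each carrier contributes
  half its cell fraction. `B` is therefore bounded by 1/2.
- `X[i,j] ~ Binomial(N[i,j], B[i,j])`, independent across loci and
  subsections *conditional on the parameters*.
- Columns of `P` are probability simplexes and `P[1,j] >= delta_normal`:
  every subsection contains normal contamination. `delta_normal` defaults
  to 1e-3 (dimensionless cell fraction); the assumption is qualitative —
  perfectly pure tumor subsections do not occur in practice — and the
  numeric floor only keeps the optimizer off the exact boundary.

Both binomial-coefficient-inclusive and -exclusive log-likelihoods appear
in the code. Reported likelihoods (observed, complete-data, genotype
scores) include the coefficients so they are comparable across software;
the EM inner loop drops them because they are constant in the parameters.
Reported likelihoods are exact — an impossible observation yields `-inf`,
never a clipped value; probabilities are clipped (at 1e-300) only inside
the optimizer and the E-step workspace.

## EM algorithm

- **E step.** All K = 2^(C−1) admissible genotype vectors are enumerated
  (capped at C = 12, i.e. 4096 vectors per locus; the clone count should
  not exceed the number of subsections anyway, or the problem is
  under-constrained). Posteriors are computed in log space with
  log-sum-exp normalization; per-clone marginals follow by summation.
- **theta update.** Closed form: `theta[c]` = mean posterior marginal of
  clone c over loci.
- **P update.** Only the tumor entries `P[2:, j]` are free variables, each
  box-constrained to `[0, 1 − delta_normal]`; the normal entry is defined
  implicitly as one minus the column's tumor mass. Since the normal clone
  carries no variants, the expected binomial objective Q1 depends on the
  tumor entries alone; its analytic gradient
  `dQ1/dP[c,j] = sum_k Z[k,c] (A[k,j]/B[k,j] − D[k,j]/(1−B[k,j])) / 2`
  (A, D the posterior-weighted variant/reference counts collapsed over
  loci) is supplied to L-BFGS-B. A quadratic penalty activates only when a
  column's tumor mass exceeds `1 − delta_normal`, and any residual
  over-mass is rescaled away afterwards; if the returned point is worse
  than the incumbent (possible after the projection), the incumbent is
  kept, so each M step never decreases the surrogate objective.
- **Initialization.** `P` columns are normalized Uniform(0,1) draws (with
  the normal fraction floored at `delta_normal`), `theta` is Uniform(0,1)
  per tumor clone. Restart r of a multi-restart fit uses seed
  `(seed + r) mod 2^31`; all randomness flows from a single master seed.
- **Convergence.** Iteration stops when the relative change of Q\* — the
  expected complete-data log-likelihood maximized in the M step — drops
  below `epsilon` (default 1e-3 relative) or after `max_iter` (1000)
  iterations. Q\*'s Bernoulli part is assembled from the marginals
  (exact, because the genotype entries are binary) and its binomial part
  from the cached E-step posterior table.
- **Genotype calls.** Marginals are thresholded at 0.5, ties rounding to
  1. On well-separated data the marginals are numerically exact 0/1, so
  the threshold is immaterial there.

### Two likelihood traces

`EMResult` carries two per-iteration traces, and the distinction matters:

- `loglik_trace` — the **observed-data log-likelihood**, a free by-product
  of each E step's normalizer. EM theory guarantees this sequence is
  non-decreasing, and the test suite asserts it to 1e-6 relative
  tolerance.
- `q_star_trace` — **Q\***, the convergence and BIC quantity. Q\* equals
  the observed log-likelihood *minus the posterior entropy*, so it is
  provably not monotone in general: on ambiguous panels (e.g. a single
  tumor subsection, where mutation presence and clone fraction are
  confounded) the entropy can grow between iterations and Q\* can dip by
  a few percent while the likelihood still improves. On well-separated
  panels the posterior entropy is ~0 and the two traces coincide.

## Model selection

`BIC = −2 Q* + K log n` with `K = (C−1)(M+S)` — one genotype bit per locus
and one frequency per subsection for each tumor clone (the normal clone is
deterministic; each frequency column loses one degree of freedom to the
simplex) — and `n = sum(N)`, the total read count. The selection table
reports the percentage BIC improvement between consecutive clone counts so
an elbow can be read off; no automatic cutoff is applied, because adding
clones whose BIC gain is marginal invites overfitting and the choice is
best left visible to the analyst.

## Simulator

The synthetic-data generator draws from the generative model itself, under
the study conditions used throughout the tests: per-subsection coverage is
`Multinomial(M × mean_coverage, uniform over loci)` with `mean_coverage`
defaulting to 1000 reads per locus (targeted deep sequencing); tumor-clone
genotype bits are `Bernoulli(genotype_p)` with `genotype_p = 0.3` by
default (a panel where roughly a third of locus-clone pairs are mutated —
mutations informative about several clones without saturating); `P`
columns are normalized Uniform(0,1) draws, except the normal subsection's
column which is set to exactly (1, 0, …, 0). The *fitted* model still
estimates that column freely, mirroring the contamination assumption.
Optional noise flips each read's allele call independently:
`X' = X − Binomial(X, e) + Binomial(N − X, e)`.

What the simulator does **not** emulate: copy-number variation (the
halving in `B` is wrong wherever copy number differs from 2), loss of
heterozygosity, overdispersed (beta-binomial) counts, mapping artifacts,
and spatial correlation between subsections. Passing recovery tests on
these simulations therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to the ways
real tumors violate them.

## Error metrics

Clone labels are arbitrary, so the estimate is compared to the truth under
the tumor-clone column permutation minimizing the genotype error; that
same permutation is reused for the frequency error. The genotype error is
the mean absolute difference over the M×(C−1) tumor genotype entries; the
frequency error is the mean absolute difference over all C×S frequency
entries. Exhaustive permutation search is used through 8 tumor clones;
beyond that a Hungarian assignment on the pairwise-mismatch matrix gives
the identical optimum because the cost is additive over matched columns.

## Phylogeny

A genotype matrix admits a mutation-unique clonal tree (every mutation
arises on exactly one edge, no back-mutation) iff the carrier-clone sets
of every pair of mutations are nested or disjoint — the two-state perfect
phylogeny condition with the all-zero normal clone as ancestral state. The
tree is built from the laminar family of distinct carrier sets: each set
becomes one edge carrying exactly its mutations, nested under the smallest
strictly containing set; each clone attaches below the smallest set
containing it. Carrier sets that are no clone's minimal set yield implied
(unlabeled) ancestor nodes — e.g. a trunk of founder mutations shared by
all tumor clones. Clones with identical genotypes share one node.

Invalid matrices are repaired by enumerating every one-bit flip applied
uniformly to a distinct genotype row pattern (flipping the bit for all
loci sharing that pattern), keeping the candidates that pass the validity
test, and rescoring each under the model with the genotype held fixed:
theta then has the closed form `mean(W[:,c])`, the posterior is pinned on
the fixed rows, and only the frequency optimization remains, restarted
from 200 random initializations by default (a far easier problem than the
full EM, so many cheap restarts are affordable). Both likelihood
conventions (with and without Bernoulli prior terms and binomial
coefficients) are reported for each candidate because published values do
not always state their convention; candidate *rankings* agree across
conventions at a fixed clone count.

Leave-one-out stability refits the model with each tumor subsection
removed (the normal is never held out), permutation-matches the held-out
genotype to the full-data one, and reports the per-fit Hamming distance
and whether the repaired trees are identical. Tree identity is decided on
a canonical form — the set of (edge mutation set, carrier clone set)
pairs — independent of internal node numbering.

## Variant screen

Stage 1 compares, per locus, the six outcome counts (A, C, G, T, deletion,
unknown) of the normal against each tumor subsection with a 2×6 Fisher
exact test (Freeman–Halton criterion: the p-value sums the null
probabilities of all fixed-margin tables no more probable than the
observed one). Tables whose fixed-margin enumeration stays under 2×10⁶
candidates are computed exactly by recursive enumeration with pruning;
larger ones by seeded Monte-Carlo over Patefield-sampled null tables
(default 10⁵ draws, standard error reported alongside). p-values are
converted to q-values by Storey's procedure (pi0 estimated from the
p-value mass above lambda = 0.5), with Benjamini–Hochberg available as the
pi0 = 1 special case; a locus is accepted when any of its comparisons
falls below the q threshold (default 0.05, configurable — a tuning
parameter of the screen, not a property of the data). Comparisons where
normal and tumor are both empty are recorded as NA and excluded from the
correction.

Stage 2 tests, for each accepted locus, tumor subsection and allele, the
2×2 table of (this allele vs the other five) × (normal vs tumor); at
p < 0.01 the allele is called increased or decreased by the direction of
the proportion shift, and an increased allele with a normal count of
exactly zero is flagged tumor-specific.

The deep-sequencing locus filter keeps loci with at least 3 normal reads
and at most 2 variant reads in the normal (the allowance absorbs
sequencing error; both bounds configurable). The remaining published
selection step — visual review for clustered nearby mutations — is a
manual call and deliberately not automated.

## Numerical and design notes

- Genotype enumeration orders vectors by binary encoding with clone 2 as
  the least-significant bit; row 0 is the all-zero genotype.
- Duplicate locus or subsection labels are rejected at panel construction.
- A locus with zero coverage everywhere contributes nothing to the
  binomial likelihood and cannot affect the fit (it still counts toward K
  in BIC, so pruning empty loci before selection is advisable).
- The structural-impossibility check in the public E step (`X > 0` where
  every genotype yields `B = 0`) is relaxed inside the EM loop: parameters
  may transiently sit on a zero bound, and there the clipped log-masses
  still order the genotypes correctly.
- Problem sizes in the test suite and acceptance script (e.g. 100
  simulations per grid point at M = 100, 10 restarts; 20 BIC replicates at
  M = 30) were chosen as the smallest designs at which the measured
  quantities are stable across seeds.

## Known limitations

- **No sequencing-error term, hence no noise robustness at deep
  coverage.** Under the model, a locus whose genotype row is all zero has
  `B = 0`, so a single variant read anywhere gives it likelihood exactly
  zero. At 1000× coverage, read-flip noise at rates as low as 1e-4 puts
  variant reads on most loci, and the maximum-likelihood fit *must*
  absorb every noise-touched locus into a low-frequency clone — measured
  on the C=3, S=8 grid point, the mean genotype error rises from 0.0
  (noise-free) to ≈0.19 at e = 1e-4 and ≈0.38 from e = 3e-4 upward. This
  is a property of the model, not of the optimizer: the truth-like
  solution has zero likelihood, so no number of restarts changes the
  outcome. An error-aware variant-read probability `B(1−e) + (1−B)e`
  would restore robustness but is intentionally not part of this model.
- Clone counts above the number of subsections leave the frequency
  problem under-constrained; the fit requires an explicit override flag.
- The likelihood surface at larger C is heavily multimodal; restart
  counts that suffice at C ≤ 3 (ten) can fail badly at C ≥ 5, which is
  visible as non-monotone Q\* across C in a selection table.
- Copy-number variation biases `B` multiplicatively and is not modeled;
  loci in regions of known aberrant copy number should be excluded
  upstream.
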