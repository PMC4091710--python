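"""Multi-sample somatic-variant screening on per-locus allele-count tables.

Two stages mirror a matched normal-vs-tumor screen on six mutually
exclusive read outcomes per locus (A, C, G, T, deletion, unknown):

1. For each (locus, tumor subsection) pair, a 2×6 Fisher exact test
   (Freeman–Halton) of the normal vs tumor outcome counts; p-values are
   converted to q-values over all tests and a locus is accepted if any of
   its comparisons falls below the q threshold.
2. For each accepted locus, per allele and tumor subsection, a 2×2 Fisher
   exact test of (this allele vs the other five) × (normal vs tumor);
   significant shifts are labeled increased/decreased, and an increased
   allele with zero normal counts is a tumor-specific mutation.

A separate coverage filter for targeted deep-sequencing panels keeps loci
with adequate normal coverage and at most a few variant reads in the
normal (tolerating sequencing error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact as _fisher_2x2
from scipy.stats import random_table

from .panel import CountsPanel

__all__ = [
    "AlleleCountTable",
    "OUTCOMES",
    "fisher_exact_2xk",
    "qvalues",
    "stage1_locus_test",
    "stage2_allele_calls",
    "deep_locus_filter",
    "read_allele_counts",
]

OUTCOMES = ("A", "C", "G", "T", "del", "unknown")

#: Exact enumeration of the 2×6 null is used when the number of tables
#: with the observed margins stays below this bound; larger tables fall
#: back to seeded Monte-Carlo sampling of the null.
MAX_EXACT_TABLES = 2_000_000


@dataclass
class AlleleCountTable:
    """Per-locus 6×S allele-count matrices; subsection 0 is the normal."""

    loci: list[str]
    subsections: list[str]
    counts: np.ndarray  # (L, 6, S) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        L, O, S = self.counts.shape
        if O != len(OUTCOMES):
            raise ValueError(f"expected {len(OUTCOMES)} outcome rows, got {O}")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be non-negative")
        if len(self.loci) != L or len(self.subsections) != S:
            raise ValueError("label lengths do not match counts shape")
        if S < 2:
            raise ValueError("need a normal and at least one tumor subsection")
        self.counts = self.counts.astype(np.int64)


def read_allele_counts(path) -> AlleleCountTable:
    """Read a long-format TSV: locus, subsection, A, C, G, T, del, unknown."""
    df = pd.read_csv(path, sep="\t")
    required = ["locus", "subsection", *OUTCOMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count table missing columns {missing}")
    loci = list(dict.fromkeys(df["locus"].astype(str)))
    subs = list(dict.fromkeys(df["subsection"].astype(str)))
    counts = np.zeros((len(loci), len(OUTCOMES), len(subs)), dtype=np.int64)
    li = {l: i for i, l in enumerate(loci)}
    si = {s: j for j, s in enumerate(subs)}
    for _, row in df.iterrows():
        counts[li[str(row["locus"])], :, si[str(row["subsection"])]] = [
            int(row[o]) for o in OUTCOMES
        ]
    return AlleleCountTable(loci=loci, subsections=subs, counts=counts)


def _log_table_prob(row1, colsums, n, r1):
    """Log null probability of a 2×K table given its margins."""
    row1 = np.asarray(row1)
    colsums = np.asarray(colsums)
    return float(
        (gammaln(colsums + 1) - gammaln(row1 + 1) - gammaln(colsums - row1 + 1)).sum()
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )


def _count_tables(colsums, r1) -> int:
    """Number of 2×K tables with the given column sums and first-row total."""
    if r1 > 5000:  # enumeration is certainly infeasible; avoid a large DP
        return MAX_EXACT_TABLES + 1
    ways = np.zeros(r1 + 1)  # float: only the magnitude vs the cap matters
    ways[0] = 1
    for c in colsums:
        new = np.zeros_like(ways)
        for t in range(r1 + 1):
            if ways[t]:
                hi = min(c, r1 - t)
                new[t : t + hi + 1] += ways[t]
        ways = new
    return int(min(ways[r1], 1e18))


def fisher_exact_2xk(
    table: np.ndarray,
    rng: np.random.Generator | None = None,
    n_resamples: int = 100_000,
) -> tuple[float, float | None]:
    """Two-sided Fisher exact p-value for a 2×K contingency table.

    Uses the Freeman–Halton criterion: the p-value sums the null
    (multivariate hypergeometric) probabilities of all tables with the
    observed margins that are no more probable than the observed table.
    Small tables are enumerated exactly; large ones are evaluated by
    seeded Monte-Carlo sampling of the null (Patefield's algorithm), in
    which case the second return value carries the standard error of the
    estimate (``None`` for exact computations).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2×K")
    colsums = table.sum(axis=0)
    keep = colsums > 0
    table = table[:, keep]
    colsums = colsums[keep]
    r1 = int(table[0].sum())
    n = int(table.sum())
    if n == 0 or r1 == 0 or r1 == n or table.shape[1] <= 1:
        return 1.0, None
    logp_obs = _log_table_prob(table[0], colsums, n, r1)
    tol = 1e-9
    if _count_tables(colsums.tolist(), r1) <= MAX_EXACT_TABLES:
        total = 0.0
        K = len(colsums)
        suffix_cap = np.concatenate([np.cumsum(colsums[::-1])[::-1], [0]])

        def rec(j, remaining, logp):
            nonlocal total
            if j == K:
                if remaining == 0 and logp <= logp_obs + tol:
                    total += np.exp(logp)
                return
            lo = max(0, remaining - int(suffix_cap[j + 1]))
            hi = min(int(colsums[j]), remaining)
            c = int(colsums[j])
            for x in range(lo, hi + 1):
                rec(
                    j + 1,
                    remaining - x,
                    logp + gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1),
                )

        base = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        rec(0, r1, base)
        return min(1.0, float(total)), None
    rng = rng or np.random.default_rng(0)
    dist = random_table([r1, n - r1], colsums)
    samples = dist.rvs(n_resamples, random_state=rng)
    logp = (
        gammaln(colsums + 1)
        - gammaln(samples[:, 0, :] + 1)
        - gammaln(colsums - samples[:, 0, :] + 1)
    ).sum(axis=1) - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    hits = int((logp <= logp_obs + tol).sum())
    p = (hits + 1) / (n_resamples + 1)
    se = float(np.sqrt(p * (1 - p) / n_resamples))
    return float(p), se


def qvalues(p: np.ndarray, method: str = "storey", lam: float = 0.5) -> np.ndarray:
    """Convert p-values to q-values.

    ``storey`` estimates the null proportion pi0 from the p-value mass
    above ``lam``; ``bh`` is the Benjamini–Hochberg special case pi0 = 1.
    NaN entries (skipped tests) propagate as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if method == "storey":
        pi0 = min(1.0, float((pv > lam).mean()) / (1.0 - lam))
        pi0 = max(pi0, 1.0 / m)
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown q-value method '{method}'")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m * pi0 / (np.arange(m) + 1)
    # enforce monotonicity from the largest p-value down
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    res = np.empty(m)
    res[order] = q
    out[ok] = res
    return out


def stage1_locus_test(
    table: AlleleCountTable,
    q_threshold: float = 0.05,
    qvalue_method: str = "storey",
    seed: int = 0,
    n_resamples: int = 100_000,
) -> pd.DataFrame:
    """Per-(locus, tumor subsection) 2×6 exact tests with FDR control.

    Returns a long DataFrame with columns locus, subsection, p, p_se, q
    and accepted (True when the locus has any comparison with q below the
    threshold).  Comparisons where normal and tumor are both empty are
    recorded as NA and excluded from the multiple-testing correction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for li, locus in enumerate(table.loci):
        normal = table.counts[li, :, 0]
        for sj in range(1, len(table.subsections)):
            tumor = table.counts[li, :, sj]
            if normal.sum() == 0 and tumor.sum() == 0:
                rows.append((locus, table.subsections[sj], np.nan, np.nan))
                continue
            p, se = fisher_exact_2xk(
                np.vstack([normal, tumor]), rng=rng, n_resamples=n_resamples
            )
            rows.append((locus, table.subsections[sj], p, se))
    df = pd.DataFrame(rows, columns=["locus", "subsection", "p", "p_se"])
    df["q"] = qvalues(df["p"].to_numpy(), method=qvalue_method)
    hit = df.groupby("locus", sort=False)["q"].transform(
        lambda s: (s < q_threshold).any()
    )
    df["accepted"] = hit.astype(bool)
    return df


def stage2_allele_calls(
    table: AlleleCountTable,
    accepted_loci,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-allele 2×2 exact tests on stage-1-accepted loci.

    For each accepted locus, tumor subsection and outcome, tests the
    allele's counts against the pooled counts of the other five outcomes,
    normal vs tumor.  An allele is 'increased' ('decreased') when the test
    is significant at ``p_threshold`` and its tumor proportion is higher
    (lower) than in the normal; otherwise 'unchanged'.  Increased alleles
    with a normal count of exactly zero are flagged tumor-specific.
    """
    accepted = set(accepted_loci)
    rows = []
    for li, locus in enumerate(table.loci):
        if locus not in accepted:
            continue
        normal = table.counts[li, :, 0]
        n_norm = int(normal.sum())
        for sj in range(1, len(table.subsections)):
            tumor = table.counts[li, :, sj]
            n_tum = int(tumor.sum())
            for oi, outcome in enumerate(OUTCOMES):
                a_norm, a_tum = int(normal[oi]), int(tumor[oi])
                if a_norm == 0 and a_tum == 0:
                    rows.append((locus, table.subsections[sj], outcome,
                                 1.0, "unchanged", False))
                    continue
                t22 = [[a_norm, n_norm - a_norm], [a_tum, n_tum - a_tum]]
                p = float(_fisher_2x2(t22).pvalue)
                status = "unchanged"
                if p < p_threshold:
                    frac_norm = a_norm / n_norm if n_norm else 0.0
                    frac_tum = a_tum / n_tum if n_tum else 0.0
                    status = "increased" if frac_tum > frac_norm else "decreased"
                tumor_specific = status == "increased" and a_norm == 0
                rows.append((locus, table.subsections[sj], outcome,
                             p, status, tumor_specific))
    df = pd.DataFrame(
        rows,
        columns=["locus", "subsection", "allele", "p", "status", "tumor_specific"],
    )
    df.attrs["p_threshold"] = p_threshold
    return df


def deep_locus_filter(
    panel: CountsPanel,
    min_normal_total: int = 3,
    max_normal_variant: int = 2,
) -> list[str]:
    """Coverage-based locus filter for targeted deep-sequencing panels.

    Keeps loci whose normal subsection has at least ``min_normal_total``
    reads and at most ``max_normal_variant`` variant-supporting reads
    (tolerating sequencing error).  The remaining published criterion —
    visual review for clustered nearby mutations — is a manual step and is
    deliberately not automated here.
    """
    keep = (panel.N[:, 0] >= min_normal_total) & (
        panel.X[:, 0] <= max_normal_variant
    )
    return [panel.loci[i] for i in np.flatnonzero(keep)]
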