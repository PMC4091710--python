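"""Domain types and TSV I/O for multi-section read-count data.

The central container is :class:`CountsPanel`, holding a pair of M×S integer
matrices over M somatic loci and S tumor subsections: ``N`` (total coverage)
and ``X`` (reads supporting the variant allele).  The first subsection is
always the matched normal; readers reorder columns so this convention holds
internally regardless of input column order.

Genotypes, clone frequencies and the Bernoulli mutation prior get thin
validated wrappers so that every downstream routine can assume its
invariants (binary entries, simplex columns, the all-zero normal clone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountsPanel",
    "GenotypeMatrix",
    "CloneFrequencies",
    "MutationPrior",
    "EMResult",
    "PanelFormatError",
    "PanelValidationError",
    "read_counts_panel",
    "write_counts_panel",
    "write_result",
    "read_result",
]

#: Default lower bound on the normal-clone fraction in every subsection.
#: The model assumes strictly positive normal contamination; this floor
#: makes the assumption numerically concrete.
DELTA_NORMAL = 1e-3


class PanelFormatError(ValueError):
    """Raised when input tables cannot be interpreted as a counts panel."""


class PanelValidationError(ValueError):
    """Raised when a matrix violates a structural invariant."""


def _as_int_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise PanelValidationError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=0):
            raise PanelValidationError(f"{name} must contain integers")
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise PanelValidationError(f"{name}[{i},{j}] is negative")
    return arr


@dataclass
class CountsPanel:
    """Paired variant/total read-count matrices over loci × subsections.

    Parameters
    ----------
    X : array-like of int, shape (M, S)
        Variant-supporting read counts.
    N : array-like of int, shape (M, S)
        Total read counts (coverage).
    loci : sequence of str
        Locus identifiers (opaque strings, e.g. ``"chr4a"``).
    subsections : sequence of str
        Subsection identifiers; index 0 is the matched normal.
    """

    X: np.ndarray
    N: np.ndarray
    loci: list[str]
    subsections: list[str]
    normal_index: int = 0

    def __post_init__(self) -> None:
        self.X = _as_int_matrix(self.X, "X")
        self.N = _as_int_matrix(self.N, "N")
        self.loci = [str(l) for l in self.loci]
        self.subsections = [str(s) for s in self.subsections]
        M, S = self.N.shape
        if self.X.shape != (M, S):
            raise PanelValidationError(
                f"X shape {self.X.shape} does not match N shape {self.N.shape}"
            )
        if M < 1 or S < 2:
            raise PanelValidationError(
                f"need at least 1 locus and 2 subsections, got M={M}, S={S}"
            )
        if len(self.loci) != M or len(self.subsections) != S:
            raise PanelValidationError("label lengths do not match matrix shape")
        if len(set(self.loci)) != M:
            raise PanelValidationError("duplicate locus labels are not allowed")
        if len(set(self.subsections)) != S:
            raise PanelValidationError("duplicate subsection labels are not allowed")
        bad = self.X > self.N
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"X exceeds N at locus '{self.loci[i]}', subsection "
                f"'{self.subsections[j]}' ({self.X[i, j]} > {self.N[i, j]})"
            )
        if self.normal_index != 0:
            # normalize: move the normal subsection to column 0
            order = [self.normal_index] + [
                j for j in range(S) if j != self.normal_index
            ]
            self.X = self.X[:, order]
            self.N = self.N[:, order]
            self.subsections = [self.subsections[j] for j in order]
            self.normal_index = 0

    @property
    def n_loci(self) -> int:
        return self.N.shape[0]

    @property
    def n_subsections(self) -> int:
        return self.N.shape[1]

    def drop_subsection(self, label: str) -> "CountsPanel":
        """Return a new panel without the named (tumor) subsection."""
        if label not in self.subsections:
            raise KeyError(label)
        j = self.subsections.index(label)
        if j == 0:
            raise PanelValidationError("cannot drop the normal subsection")
        keep = [k for k in range(self.n_subsections) if k != j]
        return CountsPanel(
            X=self.X[:, keep],
            N=self.N[:, keep],
            loci=list(self.loci),
            subsections=[self.subsections[k] for k in keep],
        )


@dataclass
class GenotypeMatrix:
    """Binary M×C genotype matrix; column 0 is the all-zero normal clone."""

    W: np.ndarray
    clone_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        if self.W.ndim != 2:
            raise PanelValidationError("W must be 2-dimensional")
        if not np.isin(self.W, (0, 1)).all():
            raise PanelValidationError("W entries must be exactly 0 or 1")
        self.W = self.W.astype(np.int8)
        if self.W[:, 0].any():
            i = int(np.argmax(self.W[:, 0]))
            raise PanelValidationError(
                f"normal clone (column 0) must be all zero; row {i} is not"
            )
        if not self.clone_labels:
            self.clone_labels = [f"C{c}" for c in range(self.W.shape[1])]
        if len(self.clone_labels) != self.W.shape[1]:
            raise PanelValidationError("clone_labels length mismatch")

    @property
    def n_clones(self) -> int:
        return self.W.shape[1]


@dataclass
class CloneFrequencies:
    """C×S clone-frequency matrix; each column is a probability simplex.

    Row 0 is the normal-clone fraction per subsection and must stay at or
    above ``delta_normal`` (non-zero normal contamination).
    """

    P: np.ndarray
    delta_normal: float = DELTA_NORMAL

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2:
            raise PanelValidationError("P must be 2-dimensional")
        if (self.P < -1e-12).any() or (self.P > 1 + 1e-12).any():
            raise PanelValidationError("P entries must lie in [0, 1]")
        colsums = self.P.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-8):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise PanelValidationError(
                f"column {j} of P sums to {colsums[j]!r}, expected 1"
            )
        if (self.P[0] < self.delta_normal - 1e-9).any():
            j = int(np.argmin(self.P[0]))
            raise PanelValidationError(
                f"normal-clone fraction {self.P[0, j]!r} in column {j} is below "
                f"the contamination floor {self.delta_normal}"
            )

    @property
    def n_clones(self) -> int:
        return self.P.shape[0]

    @property
    def n_subsections(self) -> int:
        return self.P.shape[1]


@dataclass
class MutationPrior:
    """Per-clone Bernoulli mutation probability; the normal clone is fixed at 0."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise PanelValidationError("theta must be a vector")
        if (self.theta < 0).any() or (self.theta > 1).any():
            raise PanelValidationError("theta entries must lie in [0, 1]")
        if self.theta[0] != 0:
            raise PanelValidationError("theta[0] (normal clone) must be 0")


@dataclass
class EMResult:
    """Converged output of one EM run (see :mod:`clomix.em`).

    ``loglik_trace`` holds the observed-data log-likelihood per iteration;
    EM guarantees it is non-decreasing.  ``q_star_trace`` holds the
    expected complete-data log-likelihood Q* maximized in each M step —
    the convergence and BIC quantity.  Q* differs from the observed
    log-likelihood by the posterior entropy, so on ambiguous panels it
    need not be monotone.
    """

    P: CloneFrequencies
    theta: MutationPrior
    marginals: np.ndarray          # M×C posterior P(Z_ic = 1 | data)
    W_called: GenotypeMatrix       # marginals thresholded at 0.5
    loglik_trace: np.ndarray       # per-iteration observed-data loglik
    q_star_trace: np.ndarray       # per-iteration Q* (after each M step)
    observed_loglik: float
    converged: bool
    n_iter: int
    seed: int
    optimizer_fallbacks: int = 0

    @property
    def Q_star(self) -> float:
        """Final expected complete-data log-likelihood."""
        return float(self.q_star_trace[-1])

    @property
    def n_clones(self) -> int:
        return self.P.n_clones


# ---------------------------------------------------------------------------
# TSV / JSON I/O


def _read_labeled_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise PanelFormatError(f"{path} has no data columns")
    return df


def read_counts_panel(path_X, path_N, normal_label: str | None = None) -> CountsPanel:
    """Read paired variant/total count TSVs into a validated panel.

    Both files must share one header row of subsection labels and one
    leading column of locus labels, with identical labels in identical
    order.  The normal subsection (``normal_label``, default: the first
    column) is moved to column 0.
    """
    dx = _read_labeled_tsv(path_X)
    dn = _read_labeled_tsv(path_N)
    if list(dx.index) != list(dn.index) or list(dx.columns) != list(dn.columns):
        raise PanelFormatError(
            f"label mismatch between {path_X} and {path_N}: "
            f"rows {list(dx.index)[:3]}.. vs {list(dn.index)[:3]}.., "
            f"columns {list(dx.columns)} vs {list(dn.columns)}"
        )
    subsections = [str(c) for c in dx.columns]
    if normal_label is None:
        normal_index = 0
    else:
        if normal_label not in subsections:
            raise PanelFormatError(
                f"normal subsection '{normal_label}' not among columns {subsections}"
            )
        normal_index = subsections.index(normal_label)
    return CountsPanel(
        X=dx.to_numpy(),
        N=dn.to_numpy(),
        loci=[str(i) for i in dx.index],
        subsections=subsections,
        normal_index=normal_index,
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_counts_panel(panel: CountsPanel, out_dir, prefix: str = "") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in (("X", panel.X), ("N", panel.N)):
        p = out / f"{prefix}{name}.tsv"
        _write_tsv(
            pd.DataFrame(mat, index=panel.loci, columns=panel.subsections), p
        )
        paths[name] = p
    return paths


def write_result(result: EMResult, out_dir, panel: CountsPanel | None = None) -> dict[str, Path]:
    """Serialize an EM result as labeled TSVs plus a JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    C = result.n_clones
    clones = result.W_called.clone_labels
    loci = list(panel.loci) if panel is not None else [
        f"L{i}" for i in range(result.marginals.shape[0])
    ]
    subs = list(panel.subsections) if panel is not None else [
        f"S{j}" for j in range(result.P.P.shape[1])
    ]
    paths = {}
    frames = {
        "P": pd.DataFrame(result.P.P, index=clones, columns=subs),
        "theta": pd.DataFrame({"theta": result.theta.theta}, index=clones),
        "marginals": pd.DataFrame(result.marginals, index=loci, columns=clones),
        "genotypes": pd.DataFrame(result.W_called.W, index=loci, columns=clones),
    }
    for name, df in frames.items():
        p = out / f"{name}.tsv"
        _write_tsv(df, p)
        paths[name] = p
    manifest = {
        "n_clones": C,
        "seed": int(result.seed),
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "Q_star": float(result.Q_star),
        "observed_loglik": float(result.observed_loglik),
        "loglik_trace": [float(v) for v in result.loglik_trace],
        "q_star_trace": [float(v) for v in result.q_star_trace],
        "optimizer_fallbacks": int(result.optimizer_fallbacks),
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mp
    return paths


def read_result(out_dir) -> EMResult:
    """Read back an :func:`write_result` directory (round-trip inverse)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    P = pd.read_csv(out / "P.tsv", sep="\t", index_col=0)
    theta = pd.read_csv(out / "theta.tsv", sep="\t", index_col=0)["theta"].to_numpy()
    marg = pd.read_csv(out / "marginals.tsv", sep="\t", index_col=0)
    W = pd.read_csv(out / "genotypes.tsv", sep="\t", index_col=0)
    return EMResult(
        P=CloneFrequencies(P.to_numpy()),
        theta=MutationPrior(theta),
        marginals=marg.to_numpy(),
        W_called=GenotypeMatrix(W.to_numpy(), clone_labels=[str(c) for c in W.columns]),
        loglik_trace=np.asarray(manifest["loglik_trace"], dtype=float),
        q_star_trace=np.asarray(manifest["q_star_trace"], dtype=float),
        observed_loglik=float(manifest["observed_loglik"]),
        converged=bool(manifest["converged"]),
        n_iter=int(manifest["n_iter"]),
        seed=int(manifest["seed"]),
        optimizer_fallbacks=int(manifest["optimizer_fallbacks"]),
    )
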