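"""BIC-based choice of the clone count.

The model with C clones has K = (C-1)(M+S) free parameters: one genotype
bit per locus per tumor clone and one frequency per subsection per tumor
clone (the normal clone is deterministic and each frequency column loses
one degree of freedom to the simplex constraint).  The sample size is the
total read count.  A smaller BIC indicates a better fit; the table also
reports the percentage BIC improvement between consecutive clone counts so
an elbow can be read off — no automatic cutoff is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .em import EMConfig, fit_many
from .panel import CountsPanel, EMResult

__all__ = ["free_parameters", "bic", "select_C"]


def free_parameters(C: int, M: int, S: int) -> int:
    """Free-parameter count K = (C-1)(M+S)."""
    return (C - 1) * (M + S)


def bic(result: EMResult, panel: CountsPanel) -> float:
    """BIC = -2 Q* + K log(n).

    Q* is the expected complete-data log-likelihood maximized in the last
    M step; n is the total number of read counts in the panel.
    """
    C = result.n_clones
    K = free_parameters(C, panel.n_loci, panel.n_subsections)
    n = int(panel.N.sum())
    return float(-2.0 * result.Q_star + K * np.log(n))


def select_C(
    panel: CountsPanel,
    C_range,
    config: EMConfig | None = None,
    return_results: bool = False,
):
    """Fit each clone count in ``C_range`` and tabulate BIC.

    Returns a DataFrame with one row per C: the best Q* over restarts, the
    free-parameter count, the total count n, the BIC, and the percentage
    BIC improvement relative to the previous (smaller) C.  With
    ``return_results=True`` also returns the fitted ``EMResult`` per C.
    """
    config = config or EMConfig()
    rows = []
    results: dict[int, EMResult] = {}
    for C in sorted(C_range):
        best, _ = fit_many(panel, C, config)
        results[C] = best
        rows.append(
            dict(
                C=C,
                Q_star=best.Q_star,
                K=free_parameters(C, panel.n_loci, panel.n_subsections),
                n=int(panel.N.sum()),
                BIC=bic(best, panel),
            )
        )
    table = pd.DataFrame(rows)
    prev = table["BIC"].shift(1)
    table["improvement_pct"] = 100.0 * (prev - table["BIC"]) / prev.abs()
    if return_results:
        return table, results
    return table
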