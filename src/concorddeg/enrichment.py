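"""Gene-set over-representation (hypergeometric upper tail + BH FDR).

Produces the classical pathway table: per set, the background-restricted
set size K, the overlap with the query k, the ratio k/K, the
hypergeometric upper-tail p-value and the Benjamini–Hochberg FDR across
all tested sets.  The background universe is explicit — by default the
union of all genes that survived the DEG coverage filter — because the
tail probability is meaningless without it.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io_core import DataError, GeneSetCollection, logger

ENRICH_COLUMNS = ["pathway", "K", "k", "k_over_K", "p_value", "fdr"]


def hypergeom_upper_logspace(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Summed from log-pmf terms with log-sum-exp, so extreme tails keep
    full relative accuracy.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise DataError(f"[E001] inconsistent hypergeometric arguments "
                        f"k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    xs = np.arange(k, min(K, n) + 1, dtype=float)
    logpmf = (
        gammaln(K + 1) - gammaln(xs + 1) - gammaln(K - xs + 1)
        + gammaln(N - K + 1) - gammaln(n - xs + 1) - gammaln(N - K - n + xs + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(min(np.exp(min(logsumexp(logpmf), 0.0)), 1.0))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DataError("[E002] p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Over-representation of *query_genes* in each set of *collection*.

    Sets are intersected with the background first; sets smaller than
    *min_set_size* after intersection are not tested (and do not count
    toward the BH denominator).  Rows are sorted by ascending p-value.
    """
    query = set(query_genes)
    bg = set(background)
    if not query:
        raise DataError("[E003] empty query gene list")
    if not query <= bg:
        raise DataError(f"[E004] query not contained in background "
                        f"({len(query - bg)} genes outside)")
    N, n = len(bg), len(query)
    rows = []
    for name, members in collection.sets.items():
        in_bg = members & bg
        K = len(in_bg)
        if K < min_set_size:
            continue
        k = len(in_bg & query)
        rows.append((name, K, k, k / K, hypergeom_upper_logspace(k, K, n, N)))
    if not rows:
        logger.warning("[E005] no gene set passed the size filter")
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    return out[ENRICH_COLUMNS]
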