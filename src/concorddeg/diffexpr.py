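"""Per-gene two-group differential expression on log2(CPM+1) values.

With two groups, one-way ANOVA reduces to the pooled-variance t test:
F = t^2 with p from F(1, n1 + n2 - 2).  Fold change is the difference of
group means in log2 space; the downstream concordance analysis uses only
its sign.  No multiple-testing correction is applied here — the
concordance step selects on the raw p < alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import DEG_COLUMNS, DataError
from .preprocess import NormalizedMatrix


def deg_two_group(
    m_norm: NormalizedMatrix,
    min_avg_coverage: float = 1.0,
) -> pd.DataFrame:
    """Heart-vs-blood two-group test for every gene passing the coverage filter.

    Genes whose mean normalized value across *all* cells is below
    *min_avg_coverage* are omitted.  Degenerate genes (zero pooled variance)
    get p=1 when the group means are equal and p=0 (flagged) otherwise.

    Returns a DEG table with columns ``gene, log2fc, stat, p_value,
    mean_heart, mean_blood, n_heart, n_blood, dataset_id`` (plus a boolean
    ``degenerate`` column).
    """
    groups = np.asarray(m_norm.cell_group)
    heart = groups == "heart"
    blood = groups == "blood"
    n1, n2 = int(heart.sum()), int(blood.sum())
    if n1 < 2 or n2 < 2:
        raise DataError(f"[D001] both groups need >= 2 cells (heart={n1}, blood={n2})")

    vals = m_norm.values
    coverage = vals.mean(axis=1)
    keep = coverage >= min_avg_coverage
    vals = vals[keep]
    genes = [g for g, k in zip(m_norm.genes, keep) if k]

    x1, x2 = vals[:, heart], vals[:, blood]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se2 = pooled * (1.0 / n1 + 1.0 / n2)

    lfc = m1 - m2
    degenerate = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
    F = np.where(degenerate, np.inf, t * t)
    p = np.empty_like(lfc)
    ok = ~degenerate
    p[ok] = stats.f.sf(F[ok], 1, df)
    # zero pooled variance: identical groups -> p=1; separated constants -> p=0
    p[degenerate & (lfc == 0)] = 1.0
    p[degenerate & (lfc != 0)] = 0.0
    F = np.where(degenerate & (lfc == 0), 0.0, F)

    out = pd.DataFrame(
        {
            "gene": genes,
            "log2fc": lfc,
            "stat": F,
            "p_value": p,
            "mean_heart": m1,
            "mean_blood": m2,
            "n_heart": n1,
            "n_blood": n2,
            "dataset_id": m_norm.dataset_id,
            "degenerate": degenerate & (lfc != 0),
        }
    )
    return out[DEG_COLUMNS + ["degenerate"]]


def direction(log2fc: float | np.ndarray) -> int | np.ndarray:
    """Sign of the fold change: +1, -1, or 0 for an exactly zero change."""
    arr = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("[D002] non-finite log2fc")
    signs = np.sign(arr).astype(int)
    return int(signs) if signs.ndim == 0 else signs
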