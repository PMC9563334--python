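"""Per-cluster biomarker extraction and reference-profile similarity.

A cluster's biomarkers are the genes most over-expressed in it relative
to all other cells: fold change (ratio scale, from the difference of
log2 means) at least 1.5 and overall mean coverage at least 1.0, ranked
by fold change and truncated to the top 20.  The biomarker list is then
scored against a panel of reference expression profiles (one column per
cell type, e.g. B-cell subtypes): per cell type, the score is the mean
over biomarker genes of the reference expression z-scored across cell
types, so a type whose profile is distinctively high on the biomarkers
ranks first.  The metric is invariant to per-gene affine rescaling of
the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import DataError, logger
from .preprocess import NormalizedMatrix

BIOMARKER_COLUMNS = ["cluster", "gene", "fold_change", "mean_coverage"]


def compute_biomarkers(
    m_norm: NormalizedMatrix,
    fc_threshold: float = 1.5,
    min_avg: float = 1.0,
    top_n: int = 20,
) -> pd.DataFrame:
    """Top over-expressed genes per cluster vs all other cells.

    fold_change = 2^(mean_in - mean_out) on log2(CPM+1) values; genes with
    fold_change >= *fc_threshold* and overall mean >= *min_avg* qualify,
    ranked by fold change (ties broken by symbol), truncated to *top_n*.
    """
    if m_norm.cell_cluster is None:
        raise DataError("[B001] matrix has no cluster labels")
    clusters = np.asarray(m_norm.cell_cluster)
    ids = sorted(set(clusters), key=str)
    if len(ids) < 2:
        raise DataError("[B002] biomarker profiling needs >= 2 clusters")
    overall = m_norm.values.mean(axis=1)
    rows = []
    for cid in ids:
        inside = clusters == cid
        mean_in = m_norm.values[:, inside].mean(axis=1)
        mean_out = m_norm.values[:, ~inside].mean(axis=1)
        fc = np.exp2(mean_in - mean_out)
        ok = (fc >= fc_threshold) & (overall >= min_avg)
        sub = pd.DataFrame(
            {
                "cluster": cid,
                "gene": [g for g, m in zip(m_norm.genes, ok) if m],
                "fold_change": fc[ok],
                "mean_coverage": overall[ok],
            }
        )
        sub = sub.sort_values(["fold_change", "gene"], ascending=[False, True],
                              kind="mergesort").head(top_n)
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)[BIOMARKER_COLUMNS]


def read_reference_profiles(path) -> pd.DataFrame:
    """Reference expression CSV: gene rows, one column per cell type."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise DataError("[B003] reference profiles contain negative values")
    if df.index.duplicated().any():
        raise DataError("[B004] duplicate genes in reference profiles")
    return df


def reference_similarity(
    biomarker_genes,
    refs: pd.DataFrame,
) -> list[tuple[str, float]]:
    """Score each reference cell type against a biomarker gene list.

    score(type) = mean over biomarker genes of the reference expression
    z-scored across cell types; returned in descending order.  Biomarker
    genes absent from the reference universe are logged and skipped.
    """
    genes = list(biomarker_genes)
    present = [g for g in genes if g in refs.index]
    missing = sorted(set(genes) - set(present))
    if not present:
        raise DataError("[B005] no biomarker gene present in the reference universe")
    if missing:
        logger.warning("[B006] %d biomarker genes absent from reference: %s",
                       len(missing), missing[:10])
    sub = refs.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / sd, 0.0)
    scores = z.mean(axis=0)
    if np.allclose(scores, scores[0]):
        logger.warning("[B007] all reference profiles score identically (tie)")
    order = np.argsort(-scores, kind="stable")
    return [(str(refs.columns[i]), float(scores[i])) for i in order]
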