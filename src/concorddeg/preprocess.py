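"""Normalization, feature filtering and marker-based cluster selection.

Normalization is counts-per-million followed by a +1 pseudocount and log2,
the standard single-cell transform.  The two feature filters mirror the
stated rules: genes zero in >= 99% of cells are dropped (on raw counts),
and genes whose normalized value is <= 1.0 in at least 90% of cells are
dropped.  Both boundaries are treated as exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .io_core import CountMatrix, DataError, logger


@dataclass
class NormalizedMatrix:
    """log2(CPM + 1) values on the same axes as the source CountMatrix."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # genes x cells, float
    cell_group: np.ndarray
    cell_cluster: Optional[np.ndarray] = None
    dataset_id: str = "dataset"
    species: str = "human"

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def drop_zero_total_cells(m: CountMatrix) -> CountMatrix:
    """Remove cells whose total count is zero, logging their ids."""
    totals = m.counts.sum(axis=0)
    keep = totals > 0
    if keep.all():
        return m
    dropped = [c for c, k in zip(m.cells, keep) if not k]
    logger.warning("[P001] dropped %d zero-total cells: %s", len(dropped), dropped[:10])
    return CountMatrix(
        m.genes,
        [c for c, k in zip(m.cells, keep) if k],
        m.counts[:, keep],
        m.cell_group[keep],
        None if m.cell_cluster is None else m.cell_cluster[keep],
        m.dataset_id,
        m.species,
    )


def normalize_log2_cpm(m: CountMatrix) -> NormalizedMatrix:
    """value = log2(count / cell_total * 1e6 + 1).

    Raises on zero-total cells: callers must drop them first (see
    :func:`drop_zero_total_cells`), they are never imputed.
    """
    totals = m.counts.sum(axis=0, dtype=np.float64)
    zero = totals == 0
    if zero.any():
        offenders = [c for c, z in zip(m.cells, zero) if z]
        raise DataError(f"[P002] zero-total cells cannot be normalized: {offenders[:10]}")
    cpm = m.counts / totals[None, :] * 1e6
    return NormalizedMatrix(
        list(m.genes),
        list(m.cells),
        np.log2(cpm + 1.0),
        m.cell_group.copy(),
        None if m.cell_cluster is None else m.cell_cluster.copy(),
        m.dataset_id,
        m.species,
    )


def _subset_genes(m, keep: np.ndarray):
    genes = [g for g, k in zip(m.genes, keep) if k]
    if not genes:
        logger.warning("[P003] feature filter removed every gene")
    arr = m.counts if isinstance(m, CountMatrix) else m.values
    kwargs = dict(
        cell_group=m.cell_group,
        cell_cluster=m.cell_cluster,
        dataset_id=m.dataset_id,
        species=m.species,
    )
    if isinstance(m, CountMatrix):
        return CountMatrix(genes, m.cells, arr[keep], **kwargs)
    return NormalizedMatrix(genes, m.cells, arr[keep], **kwargs)


def filter_features_zero_fraction(m: CountMatrix, cutoff: float = 0.99) -> CountMatrix:
    """Keep a gene iff its fraction of zero-count cells is < *cutoff*.

    A gene zero in exactly 99% of cells sits on the boundary and is excluded.
    """
    if not (0.0 < cutoff <= 1.0):
        raise DataError(f"[P004] cutoff must be in (0, 1], got {cutoff}")
    zero_frac = (m.counts == 0).mean(axis=1)
    return _subset_genes(m, zero_frac < cutoff)


def filter_features_low_value(
    m_norm: NormalizedMatrix, value: float = 1.0, fraction: float = 0.90
) -> NormalizedMatrix:
    """Drop genes whose normalized value is <= *value* in at least *fraction* of cells."""
    if value < 0 or not (0.0 < fraction <= 1.0):
        raise DataError(f"[P005] invalid low-value filter ({value}, {fraction})")
    low_frac = (m_norm.values <= value).mean(axis=1)
    return _subset_genes(m_norm, low_frac < fraction)


def select_clusters_by_marker(
    m_norm: NormalizedMatrix,
    marker_gene: str,
    method: str = "2sd",
    threshold: float | None = None,
) -> set:
    """Select clusters with high expression of a marker gene (e.g. MS4A1 for B cells).

    ``method="2sd"``: a cluster is selected when its mean marker expression is
    at least mean + 2*SD of the *other* clusters' means.  ``method="threshold"``
    selects clusters whose mean exceeds a fixed value.  Both are reproducible
    stand-ins for a visual UMAP-based call.
    """
    if m_norm.cell_cluster is None:
        raise DataError("[P010] matrix has no cluster labels")
    if marker_gene not in m_norm.genes:
        raise DataError(f"[P011] marker gene {marker_gene!r} absent from matrix")
    clusters = np.asarray(m_norm.cell_cluster)
    ids = sorted(set(clusters), key=str)
    if len(ids) < 2:
        raise DataError("[P012] marker-based selection needs >= 2 clusters")
    row = m_norm.values[m_norm.genes.index(marker_gene)]
    means = {cid: float(row[clusters == cid].mean()) for cid in ids}
    selected = set()
    if method == "2sd":
        for cid in ids:
            others = np.array([means[o] for o in ids if o != cid])
            cut = others.mean() + 2.0 * others.std(ddof=1 if len(others) > 1 else 0)
            if means[cid] >= cut and means[cid] > others.mean():
                selected.add(cid)
    elif method == "threshold":
        if threshold is None:
            raise DataError("[P013] method='threshold' requires a threshold value")
        selected = {cid for cid in ids if means[cid] >= threshold}
    else:
        raise DataError(f"[P014] unknown selection method {method!r}")
    if not selected:
        logger.warning("[P015] no cluster passed marker selection for %s", marker_gene)
    return selected
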