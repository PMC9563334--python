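"""Domain containers and readers/writers for every external format.

All other modules consume only the types defined here: integer count
matrices (MatrixMarket triplet or dense CSV), GMT gene-set collections,
two-column ortholog symbol maps, DEG summary tables (TSV), histology
field-count tables (CSV), and the YAML/JSON analysis configuration.

Warnings and errors are routed through one logger (``concorddeg``) and
carry machine-readable codes of the form ``[Cxxx]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite

logger = logging.getLogger("concorddeg")


class DataError(ValueError):
    """Invalid input data (malformed file, broken invariant)."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


def _warn(code: str, msg: str) -> None:
    logger.warning("[%s] %s", code, msg)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: canonical column order of a DEG summary table
DEG_COLUMNS = [
    "gene",
    "log2fc",
    "stat",
    "p_value",
    "mean_heart",
    "mean_blood",
    "n_heart",
    "n_blood",
    "dataset_id",
]

#: canonical columns of a histology field-count table
FIELD_COUNT_COLUMNS = [
    "case_id",
    "diagnosis",
    "source",
    "region",
    "compartment",
    "cell_type",
    "count",
    "n_fields",
]


@dataclass
class CountMatrix:
    """Integer gene-by-cell count matrix with per-cell tissue labels.

    Parameters
    ----------
    genes : ordered gene symbols (unique within a matrix).
    cells : ordered cell identifiers.
    counts : non-negative integer array of shape ``(len(genes), len(cells))``.
    cell_group : per-cell label, each ``"heart"`` or ``"blood"``.
    cell_cluster : optional per-cell cluster identifier.
    dataset_id, species : provenance; ``species`` is ``"human"`` or ``"mouse"``.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    cell_group: np.ndarray
    cell_cluster: Optional[np.ndarray] = None
    dataset_id: str = "dataset"
    species: str = "human"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise DataError("[C001] non-integer count values in matrix")
            self.counts = as_int
        if self.counts.min(initial=0) < 0:
            raise DataError("[C002] negative count values in matrix")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise DataError(
                f"[C003] counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Index(self.genes)
            first = dupes[dupes.duplicated()][0]
            raise DataError(f"[C004] duplicate gene symbol: {first!r}")
        self.cell_group = np.asarray(self.cell_group, dtype=object)
        if self.cell_group.shape[0] != len(self.cells):
            raise DataError("[C005] cell_group length does not match cells")
        bad = set(self.cell_group) - {"heart", "blood"}
        if bad:
            raise DataError(f"[C006] cell_group labels outside {{heart, blood}}: {sorted(bad)}")
        if self.cell_cluster is not None:
            self.cell_cluster = np.asarray(self.cell_cluster, dtype=object)
            if self.cell_cluster.shape[0] != len(self.cells):
                raise DataError("[C007] cell_cluster length does not match cells")
        if self.species not in {"human", "mouse"}:
            raise DataError(f"[C008] species must be human or mouse, got {self.species!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DataError(f"[C010] empty gene set {name!r}")


@dataclass
class OrthologMap:
    """One-to-one symbol pairs (species A symbol, species B symbol)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_syms = [a for a, _ in self.pairs]
        b_syms = [b for _, b in self.pairs]
        if len(set(a_syms)) != len(a_syms) or len(set(b_syms)) != len(b_syms):
            raise DataError("[C011] ortholog map is not one-to-one")

    def b_to_a(self) -> dict[str, str]:
        """Mapping species-B symbol -> species-A symbol, case-insensitive keys."""
        return {b.upper(): a for a, b in self.pairs}


@dataclass
class AnalysisConfig:
    """All stated thresholds of the analysis, with the published defaults."""

    alpha: float = 0.05
    zero_fraction_cutoff: float = 0.99
    low_value_cutoff: float = 1.0
    low_value_fraction: float = 0.90
    min_avg_coverage: float = 1.0
    fc_threshold_biomarker: float = 1.5
    top_n_biomarkers: int = 20
    top_n_signature: int = 200
    p0_mode: str = "auto"
    p0_fixed: float = 0.25
    seed: int = 0
    exclusion_list: Optional[set[str]] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "zero_fraction_cutoff", "low_value_fraction", "p0_fixed"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"[C020] {name} must be in (0, 1], got {v}")
        if self.p0_mode not in {"auto", "fixed"}:
            raise ConfigError(f"[C021] p0_mode must be auto or fixed, got {self.p0_mode!r}")
        if int(self.seed) != self.seed:
            raise ConfigError("[C022] seed must be an integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from YAML or JSON; unknown keys are an error, never silently dropped."""
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        if doc is None:
            doc = {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"[C023] unknown config keys: {sorted(unknown)}")
        if "exclusion_list" in doc and doc["exclusion_list"] is not None:
            doc["exclusion_list"] = set(doc["exclusion_list"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# Count matrices: MTX triplet and dense CSV
# ---------------------------------------------------------------------------


def _read_metadata(metadata_path: str | Path, cells: Sequence[str]) -> tuple[np.ndarray, Optional[np.ndarray]]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns or "group" not in meta.columns:
        raise DataError("[C030] metadata must have columns cell_id and group")
    meta = meta.set_index("cell_id")
    missing = [c for c in cells if c not in meta.index]
    if missing:
        raise DataError(f"[C031] metadata missing cell id {missing[0]!r} "
                        f"({len(missing)} cells unannotated)")
    groups = meta.loc[list(cells), "group"].to_numpy(dtype=object)
    clusters = None
    if "cluster" in meta.columns:
        clusters = meta.loc[list(cells), "cluster"].to_numpy(dtype=object)
    return groups, clusters


def read_counts(
    path: str | Path,
    format: str = "mtx",
    metadata_path: str | Path | None = None,
    dataset_id: str = "dataset",
    species: str = "human",
) -> CountMatrix:
    """Read a gene-by-cell count matrix.

    ``format="mtx"``: *path* is a directory holding ``matrix.mtx`` (genes in
    rows), ``features.tsv`` and ``barcodes.tsv``.  A transposed matrix is
    detected by an axis-length mismatch against the sidecar files and
    rejected, never silently transposed.

    ``format="csv"``: *path* is a dense CSV with gene symbols as the index
    column and cell ids as column headers.

    *metadata_path* is a TSV mapping ``cell_id`` to ``group`` (heart|blood)
    and optionally ``cluster``.
    """
    if metadata_path is None:
        raise DataError("[C032] metadata_path is required (per-cell group labels)")
    if format == "mtx":
        d = Path(path)
        raw = mmread(d / "matrix.mtx")
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        genes = (d / "features.tsv").read_text().split()
        cells = (d / "barcodes.tsv").read_text().split()
        if mat.shape == (len(cells), len(genes)) and len(genes) != len(cells):
            raise DataError(
                "[C033] matrix.mtx appears transposed (cells in rows); "
                "expected genes in rows"
            )
        if mat.shape != (len(genes), len(cells)):
            raise DataError(
                f"[C034] matrix shape {mat.shape} does not match features/barcodes "
                f"({len(genes)}, {len(cells)})"
            )
    elif format == "csv":
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        mat = df.to_numpy()
        if not np.issubdtype(mat.dtype, np.integer):
            as_int = mat.astype(np.int64)
            if not np.array_equal(as_int, mat):
                bad = np.argwhere(mat != np.floor(mat))
                g, c = bad[0]
                raise DataError(
                    f"[C001] non-integer count {mat[g, c]} at gene {genes[g]!r}, "
                    f"cell {cells[c]!r}"
                )
            mat = as_int
    else:
        raise DataError(f"[C035] unknown format {format!r}")
    groups, clusters = _read_metadata(metadata_path, cells)
    return CountMatrix(genes, cells, mat, groups, clusters, dataset_id, species)


def write_counts(m: CountMatrix, out_dir: str | Path) -> None:
    """Write an MTX triplet plus metadata.tsv under *out_dir*."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    mmwrite(str(d / "matrix.mtx"), np.asarray(m.counts))
    (d / "features.tsv").write_text("\n".join(m.genes) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(m.cells) + "\n")
    meta = pd.DataFrame({"cell_id": m.cells, "group": m.cell_group})
    if m.cell_cluster is not None:
        meta["cluster"] = m.cell_cluster
    meta.to_csv(d / "metadata.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        name = parts[0]
        members = {g for g in parts[2:] if g}
        if name in sets:
            raise DataError(f"[C040] duplicate gene-set name {name!r} (line {lineno})")
        if not members:
            _warn("C041", f"gene set {name!r} has no members; dropped")
            continue
        sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source or "na", *sorted(members)])
        for name, members in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of (species A symbol, species B symbol) pairs.

    One-to-many and many-to-one pairs are removed entirely (symbol ambiguity
    cannot be resolved from symbols alone); the number removed is logged.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["a", "b"], dtype=str)
    df = df.dropna()
    if df.empty:
        raise DataError(f"[C050] empty ortholog map: {path}")
    dup_a = df["a"].duplicated(keep=False)
    dup_b = df["b"].duplicated(keep=False)
    ambiguous = dup_a | dup_b
    if ambiguous.any():
        _warn("C051", f"removed {int(ambiguous.sum())} ambiguous ortholog pairs "
                      "(one-to-many or many-to-one)")
    kept = df[~ambiguous]
    return OrthologMap(list(kept.itertuples(index=False, name=None)))


def write_ortholog_map(m: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(m.pairs).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# DEG summary tables
# ---------------------------------------------------------------------------


def validate_deg_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the DEG-table contract; returns the frame with canonical column order."""
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"[C060] DEG table missing column {missing[0]!r}")
    p = df["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise DataError(f"[C061] p_value outside [0, 1]: {bad}")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(dtype=float))):
        raise DataError("[C062] non-finite log2fc")
    return df[DEG_COLUMNS]


def write_deg_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_deg_table(df).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "dataset_id": str})
    return validate_deg_table(df)


# ---------------------------------------------------------------------------
# Histology field-count tables
# ---------------------------------------------------------------------------


def read_field_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIELD_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"[C070] field-count table missing column {missing[0]!r}")
    counts = df["count"].to_numpy()
    if np.any(counts < 0) or not np.all(counts == np.floor(counts)):
        raise DataError("[C071] counts must be non-negative integers")
    if np.any(df["n_fields"].to_numpy() < 1):
        raise DataError("[C072] n_fields must be >= 1")
    return df[FIELD_COUNT_COLUMNS]


def write_field_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[FIELD_COUNT_COLUMNS].to_csv(path, index=False)
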