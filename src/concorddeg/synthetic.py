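"""Synthetic multi-dataset count data with planted concordance structure.

The generator emulates the study design the concordance analysis assumes:
D datasets (default 3 — two human-like, one mouse-like) of
negative-binomial gene-by-cell counts with a heart and a blood group.
A fraction of genes is conserved — differentially expressed in every
dataset with a shared fold-change direction; another fraction is
dataset-specific — differentially expressed in a single dataset with a
random direction; the rest are null.  The mouse-like dataset differs only
by title-cased symbols and ~1% ortholog dropout, matching the symbol-level
harmonization step.  Ground truth is returned for recovery tests.

A summary-level fast path (:func:`simulate_deg_summaries`) skips the count
layer and draws DEG tables directly: null p-values uniform, alternative
p-values from a normal shift proportional to lfc*sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CountMatrix, DataError, OrthologMap


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the three-dataset comparison the analysis targets:
    moderate gene panel, 200 cells per tissue group, log2 effect size 1.0,
    NB dispersion 0.5, library sizes log-uniform in [2000, 20000] so CPM
    normalization matters, 1% ortholog dropout for the mouse-like dataset.
    """

    n_datasets: int = 3
    n_genes: int = 2000
    n_cells_per_group: int = 200
    frac_conserved: float = 0.15
    frac_specific: float = 0.10
    lfc_magnitude: float = 1.0
    nb_dispersion: float = 0.5
    library_size_range: tuple[float, float] = (2000.0, 20000.0)
    ortholog_dropout: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_conserved", "frac_specific", "ortholog_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"[S001] {name} must be in [0, 1], got {v}")
        if self.frac_conserved + self.frac_specific > 1.0:
            raise DataError("[S002] frac_conserved + frac_specific > 1")
        if self.n_cells_per_group < 2:
            raise DataError("[S003] n_cells_per_group must be >= 2")
        if self.n_datasets < 1 or self.n_genes < 1:
            raise DataError("[S004] n_datasets and n_genes must be >= 1")
        if self.nb_dispersion < 0:
            raise DataError("[S005] nb_dispersion must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    conserved_genes: set[str]
    specific_genes: dict[str, set[str]]  # dataset_id -> genes
    directions: dict[str, int]           # gene -> shared sign (conserved)
    lfc: dict[str, dict[str, float]]     # dataset_id -> gene -> planted log2 fc


def _human_symbols(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(n)]


def _plant_effects(cfg: SimConfig, rng: np.random.Generator):
    """Choose conserved / specific genes, their directions and per-dataset lfc."""
    genes = _human_symbols(cfg.n_genes)
    dataset_ids = [f"ds{i}" for i in range(cfg.n_datasets)]
    n_cons = int(round(cfg.frac_conserved * cfg.n_genes))
    n_spec = int(round(cfg.frac_specific * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    conserved = [genes[i] for i in perm[:n_cons]]
    spec_pool = [genes[i] for i in perm[n_cons:n_cons + n_spec]]

    directions = {g: int(rng.choice([-1, 1])) for g in conserved}
    specific: dict[str, set[str]] = {d: set() for d in dataset_ids}
    lfc: dict[str, dict[str, float]] = {d: {} for d in dataset_ids}
    for d in dataset_ids:
        for g in conserved:
            lfc[d][g] = directions[g] * cfg.lfc_magnitude
    for g in spec_pool:
        d = dataset_ids[rng.integers(cfg.n_datasets)]
        specific[d].add(g)
        lfc[d][g] = float(rng.choice([-1, 1])) * cfg.lfc_magnitude
    truth = SimulationTruth(set(conserved), specific, directions, lfc)
    return genes, dataset_ids, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson mixture: var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_multidataset_counts(
    cfg: SimConfig,
) -> tuple[list[CountMatrix], OrthologMap, SimulationTruth]:
    """Generate D count matrices, the ortholog map, and the ground truth.

    Gene baselines are log-normal relative abundances shared across
    datasets; each cell's counts are negative binomial around
    library_size * relative_abundance, with heart-group means of planted
    genes scaled by 2^(±lfc).  The last dataset is mouse-like: symbols
    title-cased, an ``ortholog_dropout`` fraction missing from the map.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, dataset_ids, truth = _plant_effects(cfg, rng)

    base = rng.lognormal(mean=1.0, sigma=1.2, size=cfg.n_genes)
    base_prob = base / base.sum()
    lo, hi = cfg.library_size_range

    matrices = []
    for di, did in enumerate(dataset_ids):
        is_mouse = di == cfg.n_datasets - 1 and cfg.n_datasets > 1
        n_per = cfg.n_cells_per_group
        n_cells = 2 * n_per
        groups = np.array(["heart"] * n_per + ["blood"] * n_per, dtype=object)
        libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_cells))

        scale = np.ones((cfg.n_genes, 2))  # columns: heart, blood
        for gi, g in enumerate(genes):
            if g in truth.lfc[did]:
                scale[gi, 0] = 2.0 ** truth.lfc[did][g]
        rel = base_prob[:, None] * scale
        rel = rel / rel.sum(axis=0, keepdims=True)  # renormalize per group
        col = (groups == "blood").astype(int)
        mean = rel[:, col] * libsize[None, :]
        counts = _nb_draw(rng, mean, cfg.nb_dispersion)

        symbols = [g.title() for g in genes] if is_mouse else list(genes)
        matrices.append(
            CountMatrix(
                symbols,
                [f"{did}_cell{j:04d}" for j in range(n_cells)],
                counts,
                groups,
                dataset_id=did,
                species="mouse" if is_mouse else "human",
            )
        )

    pairs = [(g, g.title()) for g in genes]
    if cfg.ortholog_dropout > 0:
        keep = rng.random(cfg.n_genes) >= cfg.ortholog_dropout
        pairs = [p for p, k in zip(pairs, keep) if k]
    return matrices, OrthologMap(pairs), truth


def simulate_deg_summaries(
    cfg: SimConfig,
) -> tuple[list[pd.DataFrame], SimulationTruth]:
    """Draw DEG summary tables directly (no count layer).

    Per gene and dataset the test statistic is z ~ N(mu, 1) with
    mu = dir * lfc * sqrt(n_cells_per_group) / 2 for planted genes and 0
    otherwise; p = 2*Phi(-|z|) and the observed log2 fold change is
    z / (sqrt(n)/2), so null genes carry uniform p and sign-symmetric
    directions.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, dataset_ids, truth = _plant_effects(cfg, rng)
    half_sqrt_n = np.sqrt(cfg.n_cells_per_group) / 2.0

    tables = []
    for did in dataset_ids:
        mu = np.array([truth.lfc[did].get(g, 0.0) * half_sqrt_n for g in genes])
        z = rng.normal(mu, 1.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        tables.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "log2fc": z / half_sqrt_n,
                    "stat": z * z,
                    "p_value": p,
                    "mean_heart": np.nan,
                    "mean_blood": np.nan,
                    "n_heart": cfg.n_cells_per_group,
                    "n_blood": cfg.n_cells_per_group,
                    "dataset_id": did,
                }
            )
        )
    return tables, truth


def simulate_field_counts(
    rate_b: float,
    rate_t: float,
    n_fields: int,
    seed: int,
    n_cases: int = 12,
) -> pd.DataFrame:
    """Poisson lymphocyte counts per high-power field for the histology arm.

    *n_fields* fields are split evenly across *n_cases* cases; each case
    row holds the summed count over its fields for one cell type, with
    region/compartment filled as myocardial interstitium (the reference
    stratum for the B-vs-T comparison).
    """
    if rate_b < 0 or rate_t < 0:
        raise DataError("[S010] rates must be >= 0")
    if n_fields < 1:
        raise DataError("[S011] n_fields must be >= 1")
    rng = np.random.default_rng(seed)
    n_cases = min(n_cases, n_fields)
    fields_per_case = np.full(n_cases, n_fields // n_cases)
    fields_per_case[: n_fields % n_cases] += 1
    rows = []
    for ci, nf in enumerate(fields_per_case):
        for ct, rate in (("B", rate_b), ("T", rate_t)):
            rows.append(
                {
                    "case_id": f"case{ci:02d}",
                    "diagnosis": "control",
                    "source": "autopsy",
                    "region": "myocardium",
                    "compartment": "interstitial",
                    "cell_type": ct,
                    "count": int(rng.poisson(rate * nf)),
                    "n_fields": int(nf),
                }
            )
    return pd.DataFrame(rows)
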