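"""Statistics for the histology arm: exact Poisson rate comparisons.

Lymphocytes are counted per high-power field (HPF); the comparisons of
interest (B vs T cells, myocardium vs epicardium, interstitial vs
intravascular) are rate comparisons with the field count as exposure.
The "Poisson test" is the exact conditional construction behind R's
two-sample ``poisson.test``: given the total count, the first count is
Binomial(x1 + x2, t1/(t1 + t2)), tested two-sided with the
minimum-likelihood convention.  Per-case counts in each group are first
screened with a single-pass ±2 SD outlier rule, then aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import binom_two_sided_logspace
from .io_core import DataError, logger

CONTRASTS = {
    "b_vs_t",
    "myocardium_vs_epicardium",
    "interstitial_vs_intravascular",
}


def exclude_outliers_2sd(values) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass ±2 SD outlier screen.

    Mean and sample SD are computed once on the full vector; a value is
    excluded iff |v - mean| > 2*SD.  No re-iteration after exclusion.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DataError(f"[H001] outlier screen needs >= 3 values, got {v.size}")
    mu = v.mean()
    sd = v.std(ddof=1)
    out = np.abs(v - mu) > 2.0 * sd
    return v[~out], v[out]


def poisson_rate_test(x1: int, t1: float, x2: int, t2: float) -> tuple[float, float]:
    """Exact two-sample Poisson rate test; returns (p, rate_ratio).

    Conditional on x1 + x2, x1 ~ Binomial(x1 + x2, t1/(t1 + t2)); the
    two-sided minimum-likelihood binomial p is returned together with
    the observed rate ratio (x1/t1) / (x2/t2).
    """
    for x in (x1, x2):
        if x < 0 or int(x) != x:
            raise DataError(f"[H002] counts must be non-negative integers, got {x}")
    if t1 <= 0 or t2 <= 0:
        raise DataError("[H003] exposures must be positive")
    if x1 + x2 < 1:
        raise DataError("[H004] both counts are zero; rate test undefined")
    p, _ = binom_two_sided_logspace(int(x1), int(x1 + x2), t1 / (t1 + t2))
    r1, r2 = x1 / t1, x2 / t2
    ratio = np.inf if r2 == 0 else r1 / r2
    return p, float(ratio)


def _aggregate(group: pd.DataFrame, label: str) -> tuple[int, float]:
    if group.empty:
        raise DataError(f"[H005] empty stratum: {label}")
    counts = group["count"].to_numpy(dtype=float)
    if len(counts) >= 3:
        kept = group[~_outlier_mask(counts)]
        n_out = len(group) - len(kept)
        if n_out:
            logger.info("[H006] %s: excluded %d outlier cases (±2 SD)", label, n_out)
    else:
        kept = group
    return int(kept["count"].sum()), float(kept["n_fields"].sum())


def _outlier_mask(v: np.ndarray) -> np.ndarray:
    mu, sd = v.mean(), v.std(ddof=1)
    return np.abs(v - mu) > 2.0 * sd


@dataclass
class ContrastResult:
    contrast: str
    label1: str
    label2: str
    x1: int
    t1: float
    x2: int
    t2: float
    rate1: float
    rate2: float
    rate_ratio: float
    p_value: float

    def to_dict(self) -> dict:
        return vars(self).copy()


def group_compare(table: pd.DataFrame, contrast: str) -> ContrastResult:
    """Run one of the stated contrasts on a field-count table.

    Per-case counts are screened with the ±2 SD rule within each group,
    then counts and exposures are summed and the exact rate test applied.
    """
    if contrast not in CONTRASTS:
        raise DataError(f"[H007] unknown contrast {contrast!r}; one of {sorted(CONTRASTS)}")
    if contrast == "b_vs_t":
        g1 = table[table["cell_type"] == "B"]
        g2 = table[table["cell_type"] == "T"]
        l1, l2 = "B", "T"
    elif contrast == "myocardium_vs_epicardium":
        b = table[table["cell_type"] == "B"]
        g1 = b[b["region"] == "myocardium"]
        g2 = b[b["region"] == "epicardium"]
        l1, l2 = "myocardium", "epicardium"
    else:
        b = table[table["cell_type"] == "B"]
        g1 = b[b["compartment"] == "interstitial"]
        g2 = b[b["compartment"] == "intravascular"]
        l1, l2 = "interstitial", "intravascular"
    x1, t1 = _aggregate(g1, l1)
    x2, t2 = _aggregate(g2, l2)
    p, ratio = poisson_rate_test(x1, t1, x2, t2)
    return ContrastResult(contrast, l1, l2, x1, t1, x2, t2,
                          x1 / t1, x2 / t2, ratio, p)


def rate_ratio_summary(table: pd.DataFrame, per_fields: int = 10) -> dict:
    """Per-cell-type mean ± SEM per *per_fields* HPF and the displayed T:B ratio.

    Per-case rates (count / n_fields * per_fields) are averaged within cell
    type; the T:B ratio of means is rounded to the nearest integer for the
    conventional "1:k" display.  With a single case the SEM is NA.
    """
    out: dict = {"cell_types": {}}
    for ct, grp in table.groupby("cell_type"):
        per_case = grp.groupby("case_id").apply(
            lambda g: g["count"].sum() / g["n_fields"].sum() * per_fields,
            include_groups=False,
        )
        mean = float(per_case.mean())
        sem = float(per_case.std(ddof=1) / np.sqrt(len(per_case))) if len(per_case) > 1 else None
        out["cell_types"][ct] = {"mean_per_10hpf": mean, "sem": sem, "n_cases": len(per_case)}
    if {"B", "T"} <= set(out["cell_types"]):
        mb = out["cell_types"]["B"]["mean_per_10hpf"]
        mt = out["cell_types"]["T"]["mean_per_10hpf"]
        if mb > 0:
            out["t_to_b_ratio"] = mt / mb
            out["display_ratio"] = f"1:{round(mt / mb)}"
    return out


def display_ratio(mean_b: float, mean_t: float) -> str:
    """The "1:k" display for two group means (k = ratio rounded to integer)."""
    if mean_b <= 0:
        raise DataError("[H008] reference mean must be positive")
    return f"1:{round(mean_t / mean_b)}"


def display_percent(k: int, n: int) -> str:
    """Whole-percent display of a proportion, e.g. 1196 of 40868 -> '3%'."""
    if n <= 0 or k < 0 or k > n:
        raise DataError("[H009] invalid proportion arguments")
    return f"{round(100.0 * k / n)}%"
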