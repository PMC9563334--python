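"""Cross-dataset fold-change-direction concordance.

The core computation: intersect the significant genes of two or more DEG
tables (after symbol-level ortholog harmonization), ask how many of them
carry the same fold-change direction in every dataset, and compare that
match count against the sign-symmetric null, under which all D independent
directions coincide with probability p0 = 2*(1/2)^D (0.25 for three
datasets).

Two exact-binomial tail conventions are provided, both computed in log
space so p-values far below the double-precision underflow threshold keep
an accurate log10:

* ``two-sided`` — the minimum-likelihood convention of R's ``binom.test``
  (the sum of all outcome probabilities not exceeding that of the observed
  count);
* ``greater-strict`` — the strict upper tail P(X > k).  This is the
  convention behind the headline concordance statistic this pipeline
  reports (703 matches among 1713 overlapping genes at p0 = 0.25 gives
  2.939621e-48).

A logistic regression of the per-gene match indicator on the reference
dataset's DEG p-value quantifies how concordance concentrates among the
strongest expression differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from .io_core import DataError, OrthologMap, logger

LN10 = np.log(10.0)
# relative slack when comparing pmf values in the minimum-likelihood tail,
# guarding against ties broken by floating-point noise (R uses the same form)
_REL_ERR = 1e-7


# ---------------------------------------------------------------------------
# Ortholog harmonization
# ---------------------------------------------------------------------------


def map_orthologs(table: pd.DataFrame, omap: OrthologMap) -> tuple[pd.DataFrame, float]:
    """Translate a species-B DEG table onto species-A symbols.

    Symbols are matched case-insensitively (human upper-case vs mouse
    title-case).  Unmapped genes are dropped; the unmatched fraction is
    logged and returned alongside the translated table.
    """
    lut = omap.b_to_a()
    keys = table["gene"].str.upper()
    mapped = keys.map(lut)
    lost = mapped.isna()
    frac_unmatched = float(lost.mean())
    if lost.all():
        raise DataError("[K001] no gene of the table maps through the ortholog map")
    if lost.any():
        logger.info("[K002] %d/%d genes without ortholog (fraction %.4f)",
                    int(lost.sum()), len(table), frac_unmatched)
    out = table[~lost].copy()
    out["gene"] = mapped[~lost]
    return out, frac_unmatched


# ---------------------------------------------------------------------------
# Overlap and matching
# ---------------------------------------------------------------------------


def overlap_significant(
    tables: Sequence[pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Join genes significant (p < alpha) in ALL tables.

    Returns one row per overlapping gene with per-dataset ``log2fc_<id>``
    and ``p_<id>`` columns and a boolean ``matched``: true iff every
    dataset assigns the same nonzero fold-change direction.
    """
    if len(tables) < 2:
        raise DataError("[K010] overlap needs >= 2 DEG tables")
    ids = [str(t["dataset_id"].iloc[0]) for t in tables]
    if len(set(ids)) != len(ids):
        ids = [f"{d}_{i}" for i, d in enumerate(ids)]
    sigs = []
    for t, did in zip(tables, ids):
        s = t.loc[t["p_value"] < alpha, ["gene", "log2fc", "p_value"]]
        s = s.rename(columns={"log2fc": f"log2fc_{did}", "p_value": f"p_{did}"})
        sigs.append(s.set_index("gene"))
    joined = sigs[0]
    for s in sigs[1:]:
        joined = joined.join(s, how="inner")
    joined = joined.sort_index()
    lfc = joined[[f"log2fc_{d}" for d in ids]].to_numpy()
    signs = np.sign(lfc)
    joined["matched"] = np.all(signs == signs[:, :1], axis=1) & np.all(signs != 0, axis=1)
    joined.attrs["dataset_ids"] = ids
    return joined.reset_index()


def null_match_probability(D: int) -> float:
    """Chance that D independent, sign-symmetric directions all coincide: 2*(1/2)^D."""
    if D < 1 or int(D) != D:
        raise DataError(f"[K020] number of datasets must be an integer >= 1, got {D}")
    return 2.0 * 0.5 ** int(D)


# ---------------------------------------------------------------------------
# Exact binomial tails in log space
# ---------------------------------------------------------------------------


def _binom_logpmf(k: np.ndarray, n: int, p0: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(p0) + (n - k) * np.log1p(-p0)
    )


def binom_two_sided_logspace(k: int, n: int, p0: float) -> tuple[float, float]:
    """Two-sided exact binomial test, minimum-likelihood convention.

    p = sum of Binomial(n, p0) pmf values not exceeding pmf(k), as in R's
    ``binom.test``.  Computed with log-gamma pmf and log-sum-exp, so the
    returned ``(p, log10_p)`` stays accurate when p underflows double
    precision (log10_p well below -300).
    """
    _check_kn(k, n, p0)
    ks = np.arange(n + 1)
    logpmf = _binom_logpmf(ks, n, p0)
    cut = logpmf[k] + np.log1p(_REL_ERR)
    log_p = float(logsumexp(logpmf[logpmf <= cut]))
    log_p = min(log_p, 0.0)
    return float(np.exp(log_p)), log_p / LN10


def binom_upper_tail_logspace(k: int, n: int, p0: float, strict: bool = True) -> tuple[float, float]:
    """Upper-tail exact binomial probability in log space.

    ``strict=True`` gives P(X > k) (the convention of the headline
    concordance statistic); ``strict=False`` gives P(X >= k).
    """
    _check_kn(k, n, p0)
    lo = k + 1 if strict else k
    if lo > n:
        return 0.0, -np.inf
    logpmf = _binom_logpmf(np.arange(lo, n + 1), n, p0)
    log_p = min(float(logsumexp(logpmf)), 0.0)
    return float(np.exp(log_p)), log_p / LN10


def _check_kn(k: int, n: int, p0: float) -> None:
    if not (0 <= k <= n) or int(k) != k or int(n) != n or n < 1:
        raise DataError(f"[K030] invalid binomial arguments k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise DataError(f"[K031] p0 must be in (0, 1), got {p0}")


# ---------------------------------------------------------------------------
# Concordance test
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    separation: bool
    n_obs: int


@dataclass
class ConcordanceResult:
    """Summary of the cross-dataset direction-concordance test."""

    D: int
    n_overlap: int
    n_matched: int
    p0: float
    p_binomial: float          # two-sided minimum-likelihood
    log10_p_binomial: float
    p_upper: float             # strict upper tail P(X > k): headline statistic
    log10_p_upper: float
    logistic: Optional[LogisticFit] = None

    def to_dict(self) -> dict:
        d = {
            "D": self.D,
            "n_overlap": self.n_overlap,
            "n_matched": self.n_matched,
            "p0": self.p0,
            "p_binomial": self.p_binomial,
            "log10_p_binomial": self.log10_p_binomial,
            "p_upper": self.p_upper,
            "log10_p_upper": self.log10_p_upper,
        }
        if self.logistic is not None:
            d["logistic"] = vars(self.logistic)
        return d


def concordance_test(
    joined: pd.DataFrame,
    p0_mode: str = "auto",
    p0_fixed: float = 0.25,
) -> ConcordanceResult:
    """Exact binomial test of the match count among overlapping DEGs."""
    if joined.empty:
        raise DataError("[K040] empty overlap: nothing to test")
    ids = joined.attrs.get(
        "dataset_ids",
        [c[len("log2fc_"):] for c in joined.columns if c.startswith("log2fc_")],
    )
    D = len(ids)
    n = int(len(joined))
    k = int(joined["matched"].sum())
    p0 = null_match_probability(D) if p0_mode == "auto" else float(p0_fixed)
    p_two, log10_two = binom_two_sided_logspace(k, n, p0)
    p_up, log10_up = binom_upper_tail_logspace(k, n, p0, strict=True)
    return ConcordanceResult(D, n, k, p0, p_two, log10_two, p_up, log10_up)


# ---------------------------------------------------------------------------
# Logistic match-probability curve
# ---------------------------------------------------------------------------


def logistic_match_curve(
    reference_pvalues: np.ndarray,
    matched_flags: np.ndarray,
    log10_scale: bool = False,
) -> LogisticFit:
    """Logit fit of the match indicator on the reference dataset's p-value.

    Maximum likelihood via IRLS with a Wald test on the slope.  Complete
    separation (including a constant response) is detected beforehand and
    reported as a flag instead of returning divergent estimates.
    """
    x = np.asarray(reference_pvalues, dtype=float)
    y = np.asarray(matched_flags, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("[K050] covariate and flags must be 1-D and equal length")
    if len(x) < 10:
        raise DataError("[K051] logistic fit needs >= 10 observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DataError("[K052] matched_flags must be binary")
    if np.ptp(x) == 0:
        raise DataError("[K053] constant covariate")
    if log10_scale:
        x = -np.log10(np.maximum(x, np.finfo(float).tiny))

    n = len(x)
    if y.min() == y.max() or x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, separation=True, n_obs=n)

    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", False):
        logger.warning("[K054] logistic IRLS did not converge; flagged as separation")
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, separation=True, n_obs=n)
    return LogisticFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        slope_p=float(fit.pvalues[1]),
        separation=False,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Conserved signature
# ---------------------------------------------------------------------------


def conserved_signature(joined: pd.DataFrame) -> pd.DataFrame:
    """Rank the direction-matched genes by aggregate significance.

    Per dataset, genes are ranked by ascending p-value (rank 1 = smallest);
    the aggregate rank is the mean of the per-dataset ranks.  Output is
    sorted by aggregate rank with ties broken lexicographically by symbol.
    """
    ids = joined.attrs.get(
        "dataset_ids",
        [c[len("log2fc_"):] for c in joined.columns if c.startswith("log2fc_")],
    )
    matched = joined[joined["matched"]].copy()
    if matched.empty:
        logger.warning("[K060] no direction-matched genes; empty signature")
        cols = ["gene"] + [f"rank_{d}" for d in ids] + ["aggregate_rank"] + [f"dir_{d}" for d in ids]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame({"gene": matched["gene"].to_numpy()})
    ranks = []
    for d in ids:
        r = matched[f"p_{d}"].rank(method="average").to_numpy()
        out[f"rank_{d}"] = r
        ranks.append(r)
    out["aggregate_rank"] = np.mean(ranks, axis=0)
    for d in ids:
        out[f"dir_{d}"] = np.sign(matched[f"log2fc_{d}"].to_numpy()).astype(int)
    out = out.sort_values(["aggregate_rank", "gene"], kind="mergesort").reset_index(drop=True)
    out.attrs["dataset_ids"] = ids
    return out


def top_n(signature: pd.DataFrame, n: int = 200) -> list[str]:
    """First *n* genes of the signature by aggregate rank (all if fewer)."""
    if n < 1:
        raise DataError(f"[K061] n must be >= 1, got {n}")
    return signature["gene"].head(n).tolist()


def remove_exclusion_genes(genes: Sequence[str], blocklist: set[str]) -> list[str]:
    """Drop blocklisted genes (e.g. dissociation artifacts), preserving order."""
    kept = [g for g in genes if g not in blocklist]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("[K062] exclusion list removed %d of %d genes", removed, len(genes))
    if not kept:
        logger.warning("[K063] exclusion list removed every gene")
    return kept
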