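# Methods

## Normalization and feature filtering

Counts are normalized per cell to counts-per-million and transformed as
log₂(CPM + 1). Cells with a zero total count cannot be normalized; they are
dropped with their ids logged, never imputed. Two feature filters are
available, both with the boundary treated as exclusion:

* **zero-fraction filter** (raw counts): a gene is removed when it is zero
  in ≥ 99% of cells (`zero_fraction_cutoff`, default 0.99);
* **low-value filter** (normalized values): a gene is removed when its
  value is ≤ 1.0 in ≥ 90% of cells (`low_value_cutoff` = 1.0,
  `low_value_fraction` = 0.90).

Both filters are idempotent. Marker-based cluster selection (e.g. calling
B-cell clusters by *MS4A1*) is in practice often a visual call on an
embedding; this package substitutes a reproducible rule — a cluster is
selected when its mean marker expression exceeds the mean of the other
clusters' means by 2 SD — with a fixed-threshold alternative. Both are
stand-ins and are labelled as such in the API documentation.

## Differential expression

Per gene, a one-way ANOVA between the heart and blood groups on
log₂(CPM+1); with two groups F = t² of the pooled-variance t statistic and
p comes from F(1, n₁+n₂−2). Genes with mean normalized value below
`min_avg_coverage` (default 1.0) across all cells are omitted. Degenerate
genes (zero pooled variance) get p = 1 when the group means are equal, and
p = 0 with a `degenerate` flag otherwise. No multiple-testing correction is
applied at this stage: the concordance step intentionally selects on the
raw p < α, because its own inference concerns the *direction* agreement,
not per-gene significance.

The fold change is the difference of group means in log₂ space. Only its
sign enters the concordance analysis, which makes the downstream result
robust to the precise fold-change definition.

## Ortholog harmonization

Mouse DEG tables are translated to human symbols through a two-column
symbol map, matched case-insensitively (human upper-case vs mouse
title-case). One-to-many and many-to-one pairs are removed entirely during
map loading — symbol data alone cannot resolve them — and the unmatched
fraction (~1% in realistic maps) is logged and returned.

## Direction concordance

Genes significant in all D datasets form the overlap; a gene is *matched*
when all D fold-change signs are equal and nonzero (an exactly zero fold
change never matches). Under the sign-symmetric null the chance-match
probability is p₀ = 2·(½)^D: 0.25 at D = 3, 0.5 at D = 2, degenerately 1
at D = 1. p₀ can also be fixed by the user (`p0_mode: fixed`) when an
analysis defines its chance level differently.

The match count k out of n is tested against Binomial(n, p₀). All tail
sums are computed from log-gamma pmf terms with log-sum-exp, so log₁₀ p is
accurate far past the double-precision underflow point (below −300). Two
conventions are exposed:

* **strict upper tail** P(X > k) — the convention used for the headline
  concordance statistic reported by `concordance_test` (`p_upper`);
  at k = 703, n = 1713, p₀ = 0.25 it gives 2.939621e-48;
* **two-sided minimum-likelihood** (`p_binomial`) — the sum of all outcome
  probabilities not exceeding pmf(k), with the same 1 + 1e-7 relative
  slack on the pmf comparison that R's `binom.test` uses; at the same
  arguments it gives 8.49e-48.

Both are reported side by side; consumers choose the convention their
comparison requires. The strict upper tail is mildly anticonservative as a
test (it excludes the observed outcome) but is retained as the primary
summary because it is the convention under which the reference value above
is defined.

The relationship between per-gene significance and matching is summarized
by a logistic regression of the match indicator on the reference dataset's
p-value (raw scale by default, −log₁₀ optional), fit by IRLS via
statsmodels with a Wald test on the slope. Complete separation — including
a constant match indicator — is detected *before* fitting and reported as
a flag with NaN estimates rather than divergent coefficients.

The conserved signature ranks matched genes by the mean of their
per-dataset p-value ranks (rank 1 = smallest p; ties averaged), with
aggregate-rank ties broken lexicographically so output order is total and
stable. The top-N cut (default 200) and an optional exclusion list (e.g.
genes induced by enzymatic tissue dissociation) are applied afterwards,
preserving order.

## Over-representation

Standard hypergeometric upper tail P(X ≥ k) per gene set, after
intersecting each set with an explicit background universe (default: the
union of genes that survived the DEG coverage filter, always logged), with
Benjamini–Hochberg step-up FDR across the sets actually tested (K ≥
`min_set_size` after intersection). The tail is summed from log-pmf terms
for relative accuracy in extreme cases. The k/K ratio is kept at full
precision and rounded only for display. p-values from proprietary
enrichment services use unknown universes and test variants; this module
makes both explicit instead of emulating any vendor.

## Biomarkers and reference similarity

Per cluster, biomarkers are genes with ratio-scale fold change
2^(mean_in − mean_out) ≥ 1.5 and overall mean coverage ≥ 1.0, ranked by
fold change, top 20 kept. Similarity of a biomarker list to reference
expression profiles (one column per cell type, e.g. B-cell subtypes) is
the mean over biomarker genes of the reference value z-scored across cell
types. The metric is deliberately transparent — it is invariant to
per-gene affine rescaling of the reference, and a reference with identical
profiles scores every type 0 (flagged as a tie). Published subtype-calling
services do not document their metric; ours is declared, not inferred.

## Histology statistics

Lymphocyte counts per high-power field (HPF) are treated as Poisson with
the number of fields as exposure. The two-sample rate comparison is the
exact conditional test: given x₁ + x₂, x₁ ~ Binomial(x₁+x₂, t₁/(t₁+t₂)),
evaluated with the two-sided minimum-likelihood binomial p — the
construction behind R's two-sample `poisson.test`. Per-case counts within
each comparison group are first screened by a single-pass ±2 SD rule (mean
and sample SD computed once on the full vector; no re-iteration), then
counts and exposures are summed. Whether screening should precede
aggregation is a design choice; it is applied per group and logged. The
"1:8" style display ratio is the ratio of group means rounded to the
nearest integer; with a single case the SEM is reported as missing.

## Synthetic data

The generator produces D datasets (default 3; the last is "mouse-like") of
negative-binomial counts: gene baselines are log-normal relative
abundances shared across datasets; cell library sizes are log-uniform in
[2000, 20000] so CPM normalization genuinely matters; counts are
Gamma–Poisson with fixed dispersion 0.5 (variance = μ + 0.5 μ²), the
minimal overdispersed count model. A fraction of genes (default 0.15) is
*conserved* — differentially expressed in every dataset with a shared
random sign and log₂ magnitude 1.0 (heart-group means scaled by 2^(±lfc),
then renormalized within group so library size stays interpretable); a
further fraction (default 0.10) is DE in one random dataset with a random
sign; the rest are null. The mouse-like dataset differs only in
title-cased symbols and ~1% random removal from the ortholog map — species
effects beyond direction are out of scope. Default group size is 200 cells.

A summary-level fast path draws DEG tables directly: per gene,
z ~ N(dir·lfc·√n/2, 1), p = 2Φ(−|z|), observed fold change z/(√n/2). Null
p-values are uniform by construction and null directions are
sign-symmetric, which is exactly the regime the concordance test assumes.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, cell-type mixtures, mean–dispersion trends. Passing recovery
tests therefore demonstrate the pipeline's correctness under its stated
assumptions, not robustness to those artifacts.

One property of real(istic) count data is worth noting: because of the +1
pseudocount, log₂(CPM+1) retains a dependence on sequencing depth, so a
chance depth imbalance between groups shifts many genes coherently. At the
count level the null distribution of DEG p-values is therefore uniform
only approximately and gene-wise dependently; calibration checks of the
*test* use data satisfying its model (normal values, or the summary-level
path), while count-level simulations are used for recovery, not
calibration.

## Problem sizes and numerical choices

The test-suite simulations use 2000 genes × 200 cells/group × 3 datasets
for recovery (recall and direction precision ≥ 0.8 against ground truth),
500 summary-level replicates for null calibration of the concordance test
(observed type-I 0.05 at nominal 0.05; the overlap for calibration is
formed at a selection threshold of 0.5 because a three-way intersection at
0.05 under a pure null is empty — direction signs are independent of
significance under the null, so the chance level is unchanged), and
exhaustive enumeration oracles for the binomial (n ≤ 60) and
hypergeometric (N ≤ 40) tails at 1e-10 relative tolerance.

Tie-breaks are lexicographic on gene symbol throughout; all sorts are
stable; every stochastic operation takes an explicit integer seed and the
pipeline writes the resolved configuration and seed to its manifest, so
identical config + seed reproduces numeric artifacts byte for byte.

## Known limitations

* Concordance uses direction only; effect-size meta-analysis is out of scope.
* The marker-based cluster selection rule and the reference-similarity
  metric are declared stand-ins for visual/vendor procedures.
* The exact conditional Poisson test is conservative for small totals, as
  all exact tests are.
* p₀ = 2^(1−D) assumes independent, sign-symmetric datasets; correlated
  datasets (shared donors, shared processing) would inflate the chance
  level, and p₀ should then be fixed by the user.
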