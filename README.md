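# concorddeg

Cross-dataset, cross-species concordance analysis of differential gene
expression, built around the question: *do tissue-resident B cells carry a
gene-expression signature that is conserved between human and mouse?*

Myocardial B cells can be compared with circulating (peripheral-blood)
B cells in several independent single-cell datasets — different cohorts,
platforms, even species. Each dataset yields its own heart-vs-blood
differentially expressed genes (DEGs). Individually these lists are noisy;
what carries evolutionary weight is whether a gene's **fold-change
direction** agrees across all datasets more often than chance. This package
implements that meta-analysis end to end, together with the supporting
histology count statistics, and ships a synthetic-data generator so every
stage runs and is testable without any external download.

## The statistic at the core

For each of *D* datasets, a per-gene two-group test (one-way ANOVA on
log₂(CPM+1), which for two groups is the pooled-variance *t* test) gives a
log₂ fold change and p-value. Genes with *p* < α in **all** datasets form
the overlap set of size *n*; *k* of them have the same nonzero sign of the
fold change everywhere. Under a sign-symmetric null the directions are
independent fair coins, so a gene matches by chance with probability

&nbsp;&nbsp;&nbsp;&nbsp;*p₀ = 2·(½)^D*  (= 0.25 for *D* = 3).

The match count is then referred to an exact Binomial(*n*, *p₀*) law,
computed in log space (log-gamma pmf + log-sum-exp) so that p-values far
below the double-precision underflow threshold keep an accurate log₁₀. Two
tail conventions are provided: the strict upper tail P(X > k) — the
convention behind the headline statistic, giving p = 2.939621e-48 for
k = 703, n = 1713, p₀ = 0.25 — and the two-sided minimum-likelihood
convention of R's `binom.test`.

Around that core: symbol-level human↔mouse ortholog harmonization,
a logistic regression of per-gene match against the reference dataset's
p-value (IRLS with complete-separation flagging), rank-aggregated
extraction of the conserved signature, hypergeometric + Benjamini–Hochberg
gene-set over-representation, per-cluster biomarker scoring against
reference expression profiles, and exact conditional Poisson rate tests
for lymphocyte counts per high-power field.

## Worked example

The bundled all-synthetic demonstration simulates three datasets (two
human-like, one mouse-like with ~1% ortholog dropout), plants a conserved
signature in 15% of 1200 genes, and runs the full pipeline:

```bash
concord-deg run --config examples/demo_config.yaml --out demo_out
```

`demo_out/concordance.json` (excerpt):

```json
{
  "D": 3,
  "n_overlap": 155,
  "n_matched": 155,
  "p0": 0.25,
  "p_binomial": 4.794036587204902e-94,
  "log10_p_binomial": -93.31929865583416
}
```

All 155 genes that were significant in every dataset agree in direction —
far beyond the 25% expected by chance (log₁₀ p ≈ −93). The logistic fit is
flagged `separation: true` because with a planted effect this strong the
match indicator is constant; the flag replaces divergent estimates. The
enrichment stage recovers the planted gene set at the top of the pathway
table (`k/K = 75/89 = 0.84`, FDR ≈ 2e-59), and the histology arm, simulated
at the observed per-field rates of 2.41 B cells and 19.36 T cells, reports
the familiar display ratio `"1:8"` with an exact-test p-value ≪ 0.001.

Every subcommand (`simulate`, `deg`, `concord`, `enrich`, `biomarkers`,
`histo`, `run`) is a thin wrapper over the library; see `concord-deg
<cmd> --help`. All stochastic stages take a single seed, and identical
config + seed yields byte-identical numeric artifacts.

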