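# All-synthetic demonstration run: three datasets (two human-like, one
# mouse-like), planted conserved signature, histology arm included.
seed: 7
simulate:
  n_datasets: 3
  n_genes: 1200
  n_cells_per_group: 150
  frac_conserved: 0.15
  frac_specific: 0.10
  lfc_magnitude: 1.0
analysis:
  alpha: 0.05
  top_n_signature: 200
histology:
  rate_b: 2.41
  rate_t: 19.36
  n_fields: 120
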