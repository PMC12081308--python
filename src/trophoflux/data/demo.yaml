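# End-to-end demonstration on small synthetic datasets.
seed: 42
stages: [ms, sc, image, metab, reference]
ms:
  n_control: 3
  n_treated: 3
  label_fractions: 0.2
  noise_cv: 0.05
  spikein_cv: 0.2
sc:
  populations:
    - {name: polar, n_cells: 250, tag: A0251, shifts: {pTE: 1.0}}
    - {name: mural, n_cells: 250, tag: A0252, shifts: {mTE: 1.0}}
  doublet_rate: 0.05
  n_genes: 800
  mean_depth: 9000.0
image:
  n_aggregates: 3
  apical_enrichment: 3.0
  noise_sd: 2.0
metab:
  n_analytes: 12
  fold_changes: 2.0
reference:
  stages: [E5, E6, E7]
  n_queries: 24
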