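# Bundled demo: a small synthetic multi-cell-type ageing EWAS run end-to-end.
seed: 11
simulate:
  n_probes: 2000
  n_individuals: 300
  cell_types: [monocyte, tcell]
  age_range: [22, 84]
  admp_fraction: 0.3
  share_probability: 0.7
  slope_range: [0.005, 0.02]
  noise_precision: 150
  dirichlet_alpha: [5.0, 5.0]
  batch_count: 2
  marker_fraction: 0.05
  missing_rate: 0.001
  detection_fail_rate: 0.002
  mixed_tissue: blood
qc:
  detection_alpha: 0.05
  probe_coverage_min: 0.99
  sample_coverage_min: 0.95
  knn_k: 5
deconvolve:
  alpha_bonf: 0.05
  delta_beta_min: 0.70
admp:
  covariates: [sex, batch]
overlap:
  criterion: "fdr:0.05"
concordance:
  discovery_criterion: "fdr:0.05"
  validation_alpha: 0.05
validate_fractions:
  discovery_criterion: "effect_size:0.002"
  validation_criteria: ["effect_size:0.002", "bonferroni:0.05", "fdr:0.05"]
power:
  sizes: [100, 200, 300]
  runs: 2
  criterion: "bonferroni:0.05"
  gold_criterion: "bonferroni:0.05"
panel:
  size: 100
  alpha: 0.05
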