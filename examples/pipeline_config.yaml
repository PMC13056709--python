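# Full-pipeline configuration for `txfidelity run --config pipeline_config.yaml`.
# With a `simulate` section the experiment is generated in-place; to analyze
# real data instead, delete `simulate` and point counts_day0/counts_day14 at
# 10x triplet directories, `cells` at a per-cell metadata CSV, and optionally
# `reference` (gene x fine-label CSV) + `reference_mapping` (fine,broad CSV).
# resolved relative to this file's directory
outdir: ../scratch/pipeline_run
seed: 8

simulate:
  n_genes: 1200
  n_cells_day0: 900
  n_cells_day14: 900
  n_markers_per_type: 40
  marker_fold: 8.0
  base_mean: 1.5
  dispersion: 0.5
  drift_sd: 0.3

mito_prefix: MT-
qc:
  min_genes: 600
  min_umis: 1000
  max_pct_mito: 8.0
  iqr_mult: 1.5
de:
  alpha: 0.05
  min_mean_count: 1.0
  pseudocount: 1.0
marker_top_n: 50
min_cells: 15
include_day14: true
n_perm: 200
nes_min: 1.5
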