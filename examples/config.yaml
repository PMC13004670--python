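# Example pipeline configuration. Unset keys fall back to defaults.
seed: 1
output_dir: humoralkit_out

stages:
  generate: true
  repertoire: true
  abundance: true
  spatial: true
  serology: true

# Point these at existing files to skip the generate stage.
inputs: {}

synthetic:
  cohort:
    n_patients_R: 4
    n_patients_NR: 6
    cells_per_sample: 200
    igg1_pc_logfc_R: 1.5
    dirichlet_precision: 60.0
    shared_clone_fraction: 0.15
  spatial:
    n_aggregates: 4
    aggregate_radius_um: 40.0
    cells_per_aggregate: 60
    min_aggregate_gap_um: 50.0
  serology:
    readout_noise_sd: 0.5

repertoire:
  key_mode: junction_aa       # junction_aa | junction_nt | vj_junction_aa
  rescue_min_umis: 3
  rescue_min_fraction: 0.6

abundance:
  group_col: response
  reference: NR
  tissue: tumor

spatial:
  link_dist_um: 10.0
  min_community_size: 10
  bandwidth_um: 20.0
  k: 10
  leiden_resolution: 1.0

serology:
  z_threshold: 3.0
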