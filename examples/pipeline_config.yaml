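# Full-pipeline configuration (synthetic mode).
# Run:  phylorange run --config examples/pipeline_config.yaml --out run_out
#
# For user mode, set mode: user and provide either `tree` + `traits`
# (a TSV with columns species, range_size_km2, climate_nb, diet_nb,
# habitat_nb, dispersal_class, wingspan_mm) or `tree` plus the raw inputs
# (occurrences, env_grid, host_tree, host_table, habitat_table,
# wingspan_table, dispersal_table) to compute the trait table first.
mode: synthetic
n_tips: 120
seed: 1
output_dir: run_out
cap: 50
n_replicates: 10
pwr_bandwidth: optimize
seeds:
  simulate: 1
  pca: 2
  hypervolume: 3
  pwr: 4
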