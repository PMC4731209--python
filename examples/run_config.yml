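# Example end-to-end run configuration for `ignorance run --config ...`.
#
# Either give a synthetic `scenario` (as here) or real inputs via
# `records_path`, `covariate_paths` and `grid`.  All randomness flows from
# `seed`; paths are relative to the working directory.

out_dir: results/example_run
seed: 42
o_half_values: [1, 2, 5, 10, 20, 50]
year_window: [2000, 2014]

scenario:
  grid: {x_min: 0, y_min: 0, cell_size: 10000, n_rows: 30, n_cols: 30}
  seed: 42
  n_roads: 4000
  n_paths: 2000
  gamma0: 1.6094379124341003      # ln 5 expected records/cell before effects
  taxon: synthetic-taxon

mcmc:
  iterations: 2000
  burn_in: 1500
  chains: 3
  seed: 42

standardize: true
boundary_mode: squeeze            # or: drop (excludes never-visited cells)
fit_covariates: [road_density, log_population_density, elevation]
threshold_target: 0.5
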