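# ignoscore

Where do citizen scientists actually look? Presence-only observation
databases (GBIF-style portals) are silent about effort: an empty grid cell
can mean a true absence or simply that no recorder ever went there.
`ignoscore` maps that uncertainty and then explains it. It is aimed at
ecologists and biodiversity-informatics practitioners who use opportunistic
records for distribution modelling, richness assessment or survey planning
and need a defensible bias layer.

The core quantity is the **half-ignorance score** of a grid cell with
`N` records of a reference taxonomic group,

```
I = O_0.5 / (N + O_0.5),        I ∈ (0, 1]
```

where `O_0.5` is the number of observations deemed enough to halve the
ignorance: `I = 1` for never-visited cells, `0.5` at `N = O_0.5`, and → 0 as
effort accumulates. With `O_0.5 = 1`, a single record means the absence of
further reports is read as 50% true absence, 50% failure to detect. Because
the right `O_0.5` is taxon- and study-dependent, analyses sweep it over
{1, 2, 5, 10, 20, 50}.

To explain the spatial pattern, per-cell scores are regressed on six
geographic accessibility covariates (elevation, slope, road density, path
density, population density and its log), one at a time, with a Bayesian
Beta regression:

```
I_i ~ Beta(μ_i φ, (1 − μ_i) φ),     logit(μ_i) = α + β₁ x_i (+ β₂ x_i²)
```

with vague priors (φ ~ Gamma(0.1, 0.1); α, β ~ Normal(0, 1000)). Linear and
quadratic terms are admitted stepwise by the Δ-deviance rule (≥ 3.84 per
added parameter, the χ²₁ 95th percentile), each best model is summarised by
its deviance-R², and the covariate values where fitted ignorance crosses
0.5 — "at least one recorder is effectively present" — are solved in closed
form with posterior intervals. A seeded synthetic-landscape generator
produces covariate layers and effort-driven counts with realistic ranges, so
the whole pipeline runs, and is tested, without any data download.

## Worked example

The four drivers under `analysis/` run the full study on a synthetic
500×500 km landscape (2500 cells of 10 km):

```
python analysis/01_simulate_landscape.py
python analysis/02_ignorance_scores.py
python analysis/03_fit_models.py
python analysis/04_thresholds.py
```

`01` simulates six covariate layers and 92,569 observation records whose
intensity rises with road access and population (15.1% of cells are never
visited). `02` sweeps `O_0.5`:

```
 o_half  mean_ignorance  frac_fully_ignorant  frac_below_half
  1.000           0.311                0.151            0.718
  5.000           0.526                0.151            0.453
 50.000           0.825                0.151            0.108
```

Mean ignorance rises with `O_0.5` (more records are demanded for the same
trust) while the fully ignorant fraction — the never-visited cells — is
`O_0.5`-invariant. `03` fits 6 covariates × 6 `O_0.5` values × 3 nested
models and tabulates the best-model R² (percent of deviance explained):

```
o_half                  1.0   2.0   5.0   10.0  20.0  50.0
elevation                6.1   6.7   7.1   7.0   6.7   5.9
log_population_density  54.3  58.2  63.4  66.6  68.7  69.4
path_density             1.5   1.7   1.8   1.8   1.7   1.5
population_density       9.6  11.9  16.1  19.8  24.3  29.7
road_density            55.0  60.2  67.2  71.8  75.6  79.0
slope                    2.5   2.8   2.9   2.8   2.9   2.3
```

Road density and log population density dominate — the generator made
effort accessibility-driven, and the analysis recovers exactly that, stably
across the whole `O_0.5` sweep. `04` then extracts the 0.5 thresholds at
`O_0.5 = 1` from the selected curves (95% posterior intervals in brackets):

```
elevation                         724 m                [698, 758]    (rising)
road_density                     0.39 km/km²           [0.383, 0.399] (falling)
log_population_density           1.73 log(people/km²)  [1.62, 1.88]  (falling)
```

Read: below ≈0.39 km of road per km² this synthetic taxon's ignorance
exceeds 0.5 (effectively less than one recorder present); above ≈724 m
elevation, likewise. The same machinery is available on real inputs through
the `ignorance` CLI (`grid-counts`, `score`, `covariates`, `fit`,
`thresholds`, `simulate`, `run` — see `ignorance --help`), e.g.

```
ignorance run --config my_run.yml --seed 42 --out-dir results/my_run
```

which writes per-`O_0.5` ignorance rasters, fit summaries, the model
comparison table, thresholds and a manifest recording the config hash.

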