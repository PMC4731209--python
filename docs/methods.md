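# Methods

## The problem

Uncontrolled citizen-science records are presence-only: a grid cell without
records of, say, dragonflies may genuinely hold no dragonflies, or may simply
never have been visited by anyone who records them. The half-ignorance score
turns per-cell record counts `N_i` of a *reference taxonomic group* (the wider
taxon whose pooled records proxy recording effort) into a spatially explicit
index of that uncertainty,

    I_i = O_0.5 / (N_i + O_0.5),

where `O_0.5` is the number of observations judged sufficient to halve the
ignorance. `I = 1` means absolute ignorance (no records), `I = 0.5` exactly
`O_0.5` records, and `I → 0` with accumulating effort. Because the right
`O_0.5` depends on the taxon, the grain and the recording culture, every
analysis here sweeps it over {1, 2, 5, 10, 20, 50} and treats stability of
conclusions across the sweep as part of the result. Records are binned on a
regular projected grid (10 km cells by default) under a half-open
`[low, high)` cell convention, with the global maximum edge assigned to the
last cell; off-grid records are dropped with a logged count rather than
raising, because ad hoc data routinely strays outside a study region.
Each taxonomic group is scored independently; there is no cross-taxon
pooling, and all records of a group count equally (no per-recorder capping).

## Covariate layers

Six layers, chosen to capture different faces of accessibility:

| layer | units | construction |
|---|---|---|
| elevation | m | block mean of the fine DEM |
| slope | % | Horn 3×3 kernel on the fine DEM, then block mean |
| road density | km/km² | clipped length per cell / cell area |
| path density | km/km² | same operator, path features |
| population density | people/km² | polygon counts spread area-weighted on a 1 km grid, block-meaned |
| log population density | log(people/km²) | natural log with offset |

Numerical choices worth knowing:

- **Slope** uses Horn's weighted finite differences (the de facto GIS
  standard) with edge-replicated borders. For a planar surface the interior
  equals the analytic gradient exactly (tested to 1e−9); edge cells see half
  of the out-of-grid gradient component, an unavoidable artefact of any
  border rule.
- **Line density** is cell-clipped length divided by cell area rather than a
  circular search-neighbourhood density. The neighbourhood variant needs a
  radius parameter that is rarely reported with published maps; the clipped
  version is parameter-free, additive over feature sets, invariant to
  polyline vertex subdivision, and exactly testable against geometry.
  Source-specific inclusion rules (dropping forestry access roads, keeping
  footpaths and hiking trails) are expressed as class filters on the feature
  file, not geometry logic.
- **Population** conserves people: Σ(cell density × cell area) equals the
  polygon totals for polygons inside the grid (tested to 1e−6 relative).
  Zero-area polygons are skipped with a warning.
- **Log transform** is the natural log (base is a free choice; it only
  rescales coefficients). The offset keeping zero-density cells finite
  defaults to the smallest positive value in the layer, or 1 if none exists.
- **Block-mean aggregation** ignores no-data cells; an all-no-data block
  stays no-data, and trailing partial blocks average over what is available.

Reprojection is out of scope: all inputs must already share the grid's
projected CRS, in metres.

## The regression model

Per covariate and per `O_0.5` value, the cell scores are modelled as

    I_i ~ Beta(a_i, b_i),  a_i = μ_i φ,  b_i = (1 − μ_i) φ,
    logit(μ_i) = α + β₁ x*_i (+ β₂ x*²_i),

one covariate at a time (the variables are strongly collinear; the question
asked of each is marginal, not partial), at three nested degrees: null,
linear, quadratic. Priors are vague: φ ~ Gamma(0.1, 0.1), coefficients
Normal with variance 1000 (SD ≈ 31.6). A precision-parameterised sampler
would read "Normal(0, 1000)" as a near-point-mass prior, so the variance
reading is the only one consistent with "uninformative"; the SD is a config
knob (`prior_coef_sd`) for anyone who disagrees.

Covariates are centred and scaled before fitting (`x*`) for sampler
stability — the quadratic column is the square of the standardised
coordinate — and every curve and threshold is reported back in original
units through the stored standardisation record.

Scores of exactly 1 (never-visited cells) sit on the boundary the Beta
likelihood excludes. The default is the Smithson–Verkuilen squeeze
`y' = (y(n−1) + ½)/n`, which keeps unsampled cells in the fit;
`boundary_mode="drop"` instead removes them, which answers a different
question ("given somebody came, what drives how much?") and is therefore
not the default.

### Sampling

The posterior over (α, β, log φ) is explored by adaptive random-walk
Metropolis: independent chains (default 3) whose joint-proposal covariance
is tuned during burn-in (scaled empirical covariance of the chain history,
Haario-style, refreshed every 50 iterations) and frozen for the retained
phase, default 5000 kept draws per chain after 2000 burn-in. φ is sampled
on the log scale with the Jacobian included, keeping positivity exact.
Chains start from a data-driven point (logit-scale least squares plus a
moment estimate of φ), jittered per chain; a start with non-finite posterior
is re-drawn up to 50 times before erroring. Convergence is summarised by
split-chain R̂ per parameter, warned above 1.1. Identical settings and seed
give bit-identical draws; chain seeds are spawned from the run seed.

The sampler contract is distributional, not algorithmic: tests enforce that
the posterior mode (found by polishing the best draw with a numerical
optimiser on the log posterior) matches an independent maximum-likelihood
fit under near-flat priors, that known parameters are recovered within
posterior uncertainty across seeded scenarios, and that 95% intervals
achieve nominal-ish coverage.

### Deviance, selection, R²

Model deviance is the plug-in `D = −2 logL` at the posterior means of
(α, β, φ) — not the posterior-mean deviance (available as `method="mean"`),
because nested plug-in differences are what the χ² threshold calibrates.
Selection is stepwise forward: linear is accepted over null iff
`D_null − D_linear ≥ 3.84` (the χ²₁ 95th percentile at printed precision,
per added parameter), then quadratic over an *accepted* linear by the same
rule; a quadratic can never be chosen when the linear term was rejected.
Under the null this selects a spurious linear term in ≈5% of replicates,
which the acceptance suite verifies empirically on 200 seeded simulations.

Deviance-R² needs one extra care with a continuous likelihood: raw −2 logL
is typically *negative* at realistic n (fitted densities exceed 1 whenever
the response marginal is more concentrated than uniform), which makes the
naive ratio `(D_null − D)/D_null` negative and meaningless. R² is therefore
computed from deviances measured against the saturated model at a common
precision (the fitted model's φ̂):

    R² = 100 · (logL_model − logL_null) / (logL_sat − logL_null),

the fraction of the null-to-saturated log-likelihood gap the model closes —
the same move classical GLMs make by evaluating the null deviance at the
model's dispersion. The saturated reference maximises each cell's Beta
log-density exactly (a Newton solve on the digamma equation, not the usual
`μ_i = y_i` shortcut, which leaks above 100% at small φ). This keeps R² in
[0, 100], 0 for the null model, ~0 for no-signal data, and monotonically
approaching 100 as φ grows under a fixed strong signal — all tested.
Residual negatives from Monte Carlo noise are clamped to 0 with a warning.

## Thresholds

Where a fitted curve crosses ignorance 0.5 is interpretable (at `O_0.5 = 1`)
as the covariate value at which at least one recorder is effectively
present. On the logit scale the crossing condition is a polynomial in `x*`
(for target 0.5 the right-hand side is exactly 0), so roots are closed-form:
one for linear fits, 0–2 for quadratics, classified rising/falling by the
derivative sign and flagged when outside the observed covariate range. A
constant curve is reported as degenerate with a warning, not as infinitely
many crossings. Every analytic root is cross-checked against a dense grid
scan of the fitted curve refined by Brent's method (agreement < 1e−6 in μ).
As an extension beyond point values, each crossing carries a 95% posterior
interval obtained by re-solving the root for each (thinned) posterior draw,
keeping per draw the root nearest the point estimate. Thresholds are
reported in original units; the standardised-scale root is recoverable from
the standardisation record.

## Synthetic landscapes

The generator replaces a national citizen-science extraction and defines the
conditions every test runs under. Defaults: a 50×50 grid of 10 km cells
(2500 cells — the order of a national 10 km grid), fine fields at 5× finer
resolution (2 km), and per-cell counts with log-intensity

    log λ_i = γ₀ + Σ_k γ_k z_k,i,   N_i ~ Poisson(λ_i),

over standardised layers, with γ₀ = ln 5 (a modest mean of 5 records per
cell before effects) and accessibility-driven effects γ_road = 1.0,
γ_log-pop = 0.8, γ_elevation = −0.5, γ_slope = −0.3, γ_path = 0.3. These
make effort rise with road access and population and fall with elevation
and steepness — the premise being tested — and produce realistic margins:
road density ~0–2 km/km², population density spanning <1 to >40,000
people/km² (log-normal marginals, σ = 2.5 on the log scale), 10–20% of
cells never visited, and a strongly negative rank correlation between road
density and ignorance. A negative-binomial option (gamma–Poisson mixture)
adds overdispersion. Elevation is a smoothed non-negative field plus a
broad regional gradient; slope is derived *from that same fine field*
through the pipeline's own Horn kernel, so the two layers are internally
consistent. Road segments are placed with probability interpolating between
uniform and proportional-to-log-population (raw population is too skewed:
it would pile the entire network into a few urban cells).

Spatial structure comes from simple moving-average smoothing; no variogram
machinery, because the regression itself ignores spatial autocorrelation —
the generator only needs plausible gradients. Two generation modes exist
deliberately: the count-based mode above exercises the full pipeline, but
transformed Poisson counts are *not* Beta distributed, so exact recovery
and calibration tests use the direct-Beta mode, which draws responses from
the fitted likelihood itself. What the generator does **not** emulate:
recorder agents with home ranges or trips, temporal effort trends, coastline
or lake masks, and spatially autocorrelated *residual* effort beyond what
the covariates induce. Passing tests therefore show the estimator and
pipeline are correct under the model's own assumptions, not that the model
is adequate for any particular real landscape.

## Problem sizes

Unit and acceptance tests run at deliberately modest sizes chosen as the
smallest that make each check sharp: n = 500 cells × 200 replicates for
the null-calibration rate (Monte Carlo SE ≈ 1.5% on a 5% rate), n = 1000 ×
20 scenarios for posterior recovery, n = 200 for MLE equivalence (where
prior influence is visible if present), and the default 2500-cell landscape
for end-to-end sign recovery. Screening fits in the analysis scripts use
2 chains × 800 kept draws; the refits behind reported curves and thresholds
use 3 × 2000.

## Known limitations

- Plug-in deviance at posterior means is slightly conservative relative to
  the MLE-based likelihood-ratio statistic (posterior means are not the
  joint mode); the empirical false-selection rate still lands at ≈5%.
- The adaptive sampler is tuned for the 2–4 parameter posteriors it serves;
  it makes no claims for higher-dimensional designs.
- One covariate per model, as designed: with strongly collinear geographic
  variables the per-covariate R² values are marginal quantities and do not
  sum to anything meaningful.
- Threshold posterior intervals condition on the selected polynomial degree;
  selection uncertainty is not propagated.
- The ESRI ASCII raster format carries no CRS; the grid's `crs_label` is a
  free-text note, and nothing reprojects.
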