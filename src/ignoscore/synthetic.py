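"""Synthetic landscapes and observation counts with the structure the analysis assumes.

The generator stands in for a national citizen-science extraction: a
rectangular grid of 10 km cells, six covariate layers with realistic ranges
(non-negative elevation with a smooth gradient, slope derived from that same
elevation field, heavily right-skewed population density spanning several
orders of magnitude, road/path densities from randomly placed line segments
whose placement can track population), and per-cell observation counts whose
log intensity is a linear function of standardised covariates — so that
ignorance correlates with accessibility by construction, mimicking recorder
behaviour.

Two generation modes serve different tests.  The count-based mode drives the
full pipeline (counts → half-ignorance → regression) for end-to-end checks;
because transformed Poisson counts are *not* Beta distributed, exact
parameter-recovery tests instead use the direct-Beta mode, which draws
responses from the very likelihood the regression fits.

Spatial smoothness comes from simple moving-average kernels: the regression
itself ignores spatial autocorrelation, so the generator only needs
plausible-looking gradients, not a variogram model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from shapely.geometry import LineString

from ignoscore.covariates import LineFeatureSet, aggregate_mean, line_density, slope_percent
from ignoscore.grid import CountRaster, CovariateLayer, GridSpec
from ignoscore.ignorance import ObservationRecord

#: Per-layer effort coefficients of the default scenario: effort rises with
#: road access and population, falls with elevation and steepness.
DEFAULT_EFFORT = {
    "road_density": 1.0,
    "log_population_density": 0.8,
    "elevation": -0.5,
    "slope": -0.3,
    "path_density": 0.3,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete generative recipe; the seed fully determines every output.

    Defaults describe a 500×500 km study region of 10 km analysis cells
    (2500 cells, the order of magnitude of a national 10 km grid) with fine
    fields simulated at a 5× finer resolution, mean observation count
    exp(gamma0) = 5 per cell, and accessibility-driven effort.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(0.0, 0.0, 10_000.0, 50, 50))
    seed: int = 0
    fine_factor: int = 5
    smooth_cells: int = 4            # moving-average half-width on the fine grid
    elevation_max: float = 1500.0    # m; field rescaled into [0, elevation_max]
    pop_log_mean: float = 1.5        # population density = exp(N(mean, sd)) people/km²
    pop_log_sd: float = 2.5
    n_roads: int = 12_000
    n_paths: int = 6_000
    segment_length_km: tuple[float, float] = (4.0, 16.0)
    road_population_tracking: float = 0.7   # 0 = uniform placement, 1 = strongly population-weighted
    gamma0: float = float(np.log(5.0))
    gamma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFORT))
    count_noise: str = "poisson"     # "poisson" | "negbin"
    negbin_dispersion: float = 1.0   # kappa; smaller = more overdispersed
    taxon: str = "synthetic-taxon"

    def __post_init__(self) -> None:
        if self.count_noise not in ("poisson", "negbin"):
            raise ValueError(f"unknown count noise model {self.count_noise!r}")
        if self.negbin_dispersion <= 0:
            raise ValueError("negbin dispersion must be positive")

    def with_(self, **changes) -> "SyntheticScenario":
        return replace(self, **changes)


def _smooth(field2d: np.ndarray, half_width: int) -> np.ndarray:
    """Separable moving-average smoothing with edge replication."""
    if half_width < 1:
        return field2d
    k = 2 * half_width + 1
    kernel = np.ones(k) / k
    padded = np.pad(field2d, half_width, mode="edge")
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)
    out = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="valid"), 0, out)
    return out


def _smooth_gaussian_field(shape: tuple[int, int], half_width: int, rng: np.random.Generator) -> np.ndarray:
    """White noise smoothed and re-standardised to zero mean, unit variance."""
    f = _smooth(rng.standard_normal(shape), half_width)
    return (f - f.mean()) / f.std()


def _random_segments(
    n: int,
    grid: GridSpec,
    length_km: tuple[float, float],
    rng: np.random.Generator,
    weight: np.ndarray | None = None,
) -> list[LineString]:
    """Random line segments; centres drawn uniformly or cell-weighted."""
    if n == 0:
        return []
    if weight is None:
        cx = rng.uniform(grid.x_min, grid.x_max, n)
        cy = rng.uniform(grid.y_min, grid.y_max, n)
    else:
        p = weight.reshape(-1) / weight.sum()
        cells = rng.choice(weight.size, size=n, p=p)
        rows, cols = np.divmod(cells, grid.n_cols)
        cx = grid.x_min + (cols + rng.uniform(0, 1, n)) * grid.cell_size
        cy = grid.y_min + (rows + rng.uniform(0, 1, n)) * grid.cell_size
    theta = rng.uniform(0, np.pi, n)
    half = rng.uniform(*length_km, n) * 1000.0 / 2.0
    return [
        LineString([(x - h * np.cos(t), y - h * np.sin(t)),
                    (x + h * np.cos(t), y + h * np.sin(t))])
        for x, y, t, h in zip(cx, cy, theta, half)
    ]


def generate_covariates(scenario: SyntheticScenario) -> dict[str, CovariateLayer]:
    """All six covariate layers of a scenario, keyed by layer name.

    Elevation is a smoothed non-negative field; slope is *derived from the
    same fine elevation field* through the pipeline's own Horn kernel, so the
    two layers are internally consistent.  Population density is an
    exponentiated smoothed field (log-normal marginals, right-skewed over
    several orders of magnitude); road and path densities come from the
    line-density operator applied to randomly placed segments, with road
    placement optionally tracking population.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=scenario.seed, spawn_key=(1,)))
    grid = scenario.grid
    f = scenario.fine_factor
    fine_shape = (grid.n_rows * f, grid.n_cols * f)
    fine_cell = grid.cell_size / f

    # elevation: smooth field + a broad regional gradient, clipped at sea level
    rough = _smooth_gaussian_field(fine_shape, scenario.smooth_cells, rng)
    gy = np.linspace(-1.0, 1.0, fine_shape[0])[:, None] * rng.uniform(0.3, 1.0)
    gx = np.linspace(-1.0, 1.0, fine_shape[1])[None, :] * rng.uniform(0.3, 1.0)
    elev_fine = rough + gy + gx
    elev_fine = elev_fine - elev_fine.min()
    elev_fine = elev_fine / elev_fine.max() * scenario.elevation_max

    slope_fine = slope_percent(elev_fine, fine_cell)

    pop_field = _smooth_gaussian_field(fine_shape, scenario.smooth_cells, rng)
    pop_fine = np.exp(scenario.pop_log_mean + scenario.pop_log_sd * pop_field)

    elevation = CovariateLayer(grid, aggregate_mean(elev_fine, f), "elevation", "m")
    slope = CovariateLayer(grid, aggregate_mean(slope_fine, f), "slope", "%")
    population = CovariateLayer(grid, aggregate_mean(pop_fine, f), "population_density", "people/km²")

    from ignoscore.covariates import log_density
    log_population = log_density(population)
    log_population.name = "log_population_density"

    w = scenario.road_population_tracking
    road_weight = None
    if w > 0:
        # interpolate between uniform placement and placement proportional to
        # log population (raw population is too skewed: it would pile the
        # whole network into a handful of urban cells)
        pw = np.log1p(population.values)
        pw = pw / pw.mean()
        road_weight = (1.0 - w) + w * pw
    roads = _random_segments(scenario.n_roads, grid, scenario.segment_length_km, rng, road_weight)
    paths = _random_segments(scenario.n_paths, grid, scenario.segment_length_km, rng, None)

    road_layer = line_density(LineFeatureSet(roads, "road"), grid)
    path_layer = line_density(LineFeatureSet(paths, "path"), grid)

    return {
        "elevation": elevation,
        "slope": slope,
        "road_density": road_layer,
        "path_density": path_layer,
        "population_density": population,
        "log_population_density": log_population,
    }


def simulate_counts(
    layers: dict[str, CovariateLayer],
    gamma0: float,
    gamma: dict[str, float],
    noise: str = "poisson",
    seed: int = 0,
    negbin_dispersion: float = 1.0,
) -> CountRaster:
    """Per-cell observation counts from a log-linear effort model.

    log lambda_i = gamma0 + sum_k gamma_k * standardised layer_k; counts are
    Poisson(lambda) or negative binomial (gamma-Poisson mixture with
    dispersion kappa, variance lambda + lambda²/kappa).
    """
    grids = {layer.grid for layer in layers.values()}
    if len(grids) != 1:
        raise ValueError("all layers must share one grid")
    grid = next(iter(grids))
    eta = np.full(grid.shape, gamma0, dtype=float)
    for name, coef in gamma.items():
        if coef == 0.0:
            continue
        if name not in layers:
            raise KeyError(f"effort coefficient for unknown layer {name!r}")
        v = layers[name].values
        eta = eta + coef * (v - v.mean()) / v.std()
    lam = np.exp(eta)
    if not np.isfinite(lam).all():
        raise ValueError("non-finite count intensity; check effort coefficients")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    if noise == "poisson":
        counts = rng.poisson(lam)
    elif noise == "negbin":
        counts = rng.poisson(lam * rng.gamma(negbin_dispersion, 1.0 / negbin_dispersion, lam.shape))
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    return CountRaster(grid=grid, counts=counts)


def simulate_scenario(scenario: SyntheticScenario) -> tuple[dict[str, CovariateLayer], CountRaster]:
    """Covariate layers plus counts for one scenario (single entry point)."""
    layers = generate_covariates(scenario)
    counts = simulate_counts(layers, scenario.gamma0, scenario.gamma,
                             noise=scenario.count_noise, seed=scenario.seed,
                             negbin_dispersion=scenario.negbin_dispersion)
    counts.taxon = scenario.taxon
    return layers, counts


def records_from_counts(counts: CountRaster, seed: int = 0, year_range: tuple[int, int] = (2000, 2014)) -> list[ObservationRecord]:
    """Expand a count raster into individual records at random in-cell positions.

    Lets the synthetic data exercise the record-gridding entry of the real
    pipeline; re-gridding the records reproduces the counts exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    grid = counts.grid
    records = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            n = int(counts.counts[row, col])
            if n == 0:
                continue
            xs = grid.x_min + (col + rng.uniform(0, 1, n)) * grid.cell_size
            ys = grid.y_min + (row + rng.uniform(0, 1, n)) * grid.cell_size
            years = rng.integers(year_range[0], year_range[1] + 1, n)
            records.extend(
                ObservationRecord(counts.taxon, float(x), float(y), int(yr))
                for x, y, yr in zip(xs, ys, years)
            )
    return records


def simulate_beta_response(
    X: np.ndarray,
    alpha: float,
    beta: np.ndarray | float,
    phi: float,
    seed: int = 0,
) -> np.ndarray:
    """Responses drawn from the Beta regression itself (direct-Beta mode).

    y_i ~ Beta(mu_i phi, (1 - mu_i) phi) with logit(mu_i) = alpha + X_i beta.
    This is the generative twin of the fitted likelihood, so posterior
    recovery of (alpha, beta, phi) is exact up to Monte Carlo error.
    """
    if not phi > 0:
        raise ValueError(f"phi must be positive, got {phi}")
    X = np.asarray(X, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if X.ndim != 2 or X.shape[1] != beta.size:
        raise ValueError(f"design {X.shape} incompatible with beta of length {beta.size}")
    mu = expit(alpha + X @ beta)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    # guard against floating-point boundary hits at extreme mu/phi
    return np.clip(y, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
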