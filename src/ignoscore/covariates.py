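"""Geographic covariate layers explaining recording effort.

Six layers drive the analysis: mean elevation (m), mean slope (%), road and
footpath density (km/km²), population density (people/km²) and its log.
They proxy different faces of accessibility — roads get recorders to a site,
paths and gentle terrain move them within it, and population density proxies
how many potential recorders live nearby.

Slope uses Horn's 3x3 finite-difference kernel (the de facto GIS standard).
Line density is cell-clipped length divided by cell area — parameter-free,
unlike search-radius density tools, and exactly testable against geometry.
Population counts attached to polygons are spread area-weighted onto a fine
(nominally 1 km) grid before block-mean aggregation to the analysis grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import LineString, box
from shapely.geometry.base import BaseGeometry

from ignoscore.grid import CovariateLayer, GridConfigError, GridSpec

logger = logging.getLogger(__name__)


@dataclass
class LineFeatureSet:
    """Polyline features (grid coordinates, metres) of one class (road | path)."""

    lines: list[LineString]
    feature_class: str = "road"

    def __post_init__(self) -> None:
        for geom in self.lines:
            if len(geom.coords) < 2:
                raise ValueError("polylines need at least two vertices")
            if not np.isfinite(np.asarray(geom.coords)).all():
                raise ValueError("polyline coordinates must be finite")


@dataclass
class PopulationPolygonSet:
    """Polygons with attached population counts (people per polygon)."""

    polygons: list[BaseGeometry]
    counts: list[float]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.counts):
            raise ValueError("polygons and counts must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("population counts must be non-negative")


def slope_percent(dem: np.ndarray, cell_size: float) -> np.ndarray:
    """Per-cell slope in percent from a fine-resolution DEM.

    Horn's method: the x/y gradients are 3x3 weighted differences

        dz/dx = ((c + 2f + i) - (a + 2d + g)) / (8 h)

    (and analogously for y), and slope% = 100 * sqrt((dz/dx)² + (dz/dy)²).
    Edge cells use edge-replicated neighbourhoods; for a planar DEM the
    interior is exactly the analytic gradient, while edge cells see half the
    out-of-grid gradient component (the replicated side is flat).
    """
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError(f"DEM must be at least 3x3, got shape {dem.shape}")
    if not cell_size > 0:
        raise ValueError(f"cell_size must be positive, got {cell_size}")
    z = np.pad(dem, 1, mode="edge")
    # neighbour stencil around each cell e:  a b c / d e f / g h i
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                   f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell_size)
    return 100.0 * np.hypot(dzdx, dzdy)


def aggregate_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean aggregation of a fine raster by an integer factor.

    Each coarse cell is the arithmetic mean of its ``factor``x``factor``
    block, ignoring no-data (NaN) cells; an all-no-data block stays NaN.
    Trailing partial blocks (dimensions not divisible by ``factor``) are
    averaged over the cells available, with a log note.
    """
    if factor < 1:
        raise GridConfigError(f"aggregation factor must be >= 1, got {factor}")
    fine = np.asarray(fine, dtype=float)
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        logger.info("raster %sx%s not divisible by %d; trailing partial blocks averaged over available cells",
                    nr, nc, factor)
    out_r, out_c = -(-nr // factor), -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = fine
    blocks = padded.reshape(out_r, factor, out_c, factor).swapaxes(1, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN blocks
        return np.nanmean(blocks, axis=(2, 3))


def line_density(lines: LineFeatureSet, grid: GridSpec, name: str | None = None) -> CovariateLayer:
    """Line density in km/km²: clipped polyline length per cell / cell area."""
    density = np.zeros(grid.shape)
    if lines.lines:
        tree = STRtree(lines.lines)
        area_km2 = grid.cell_area_km2
        for row in range(grid.n_rows):
            y0 = grid.y_min + row * grid.cell_size
            for col in range(grid.n_cols):
                x0 = grid.x_min + col * grid.cell_size
                cell = box(x0, y0, x0 + grid.cell_size, y0 + grid.cell_size)
                length_m = 0.0
                for idx in tree.query(cell):
                    length_m += lines.lines[idx].intersection(cell).length
                density[row, col] = (length_m / 1000.0) / area_km2
    return CovariateLayer(grid=grid, values=density,
                          name=name or f"{lines.feature_class}_density", units="km/km²")


def population_density(polygons: PopulationPolygonSet, fine_grid: GridSpec) -> CovariateLayer:
    """Area-weighted population density (people/km²) on the fine grid.

    Each polygon contributes its own density (count / polygon area) to every
    fine cell it overlaps, weighted by the overlap fraction; total population
    is conserved for polygons fully inside the grid.  Aggregate with
    :func:`aggregate_mean` for the coarse analysis layer.
    """
    values = np.zeros(fine_grid.shape)
    cell_area_m2 = fine_grid.cell_size ** 2
    kept: list[tuple[BaseGeometry, float]] = []
    for poly, count in zip(polygons.polygons, polygons.counts):
        if poly.area <= 0:
            logger.warning("skipping zero-area population polygon (count=%s)", count)
            continue
        kept.append((poly, count / poly.area))  # density in people/m²
    if kept:
        tree = STRtree([p for p, _ in kept])
        for row in range(fine_grid.n_rows):
            y0 = fine_grid.y_min + row * fine_grid.cell_size
            for col in range(fine_grid.n_cols):
                x0 = fine_grid.x_min + col * fine_grid.cell_size
                cell = box(x0, y0, x0 + fine_grid.cell_size, y0 + fine_grid.cell_size)
                people = 0.0
                for idx in tree.query(cell):
                    poly, dens_m2 = kept[idx]
                    people += dens_m2 * poly.intersection(cell).area
                values[row, col] = people / cell_area_m2 * 1e6  # people/m² -> people/km²
    return CovariateLayer(grid=fine_grid, values=values, name="population_density", units="people/km²")


def log_density(layer: CovariateLayer, offset: float | None = None) -> CovariateLayer:
    """Natural-log transform ln(value + offset) of a non-negative density layer.

    The log view resolves effects at the lowest densities, where most of a
    sparsely populated country's land area sits.  The offset keeps zero-density
    cells finite; it defaults to the smallest positive value in the layer
    (or 1 if there is none).
    """
    vals = layer.values
    if np.nanmin(vals) < 0:
        raise ValueError("log_density requires non-negative values")
    if offset is None:
        positive = vals[np.isfinite(vals) & (vals > 0)]
        offset = float(positive.min()) if positive.size else 1.0
    if offset <= 0:
        raise GridConfigError(f"offset must be positive, got {offset}")
    return CovariateLayer(grid=layer.grid, values=np.log(vals + offset),
                          name=f"log_{layer.name}", units=f"log({layer.units})")


def aggregate_layer(layer: CovariateLayer, factor: int) -> CovariateLayer:
    """Block-mean a fine CovariateLayer onto the coarsened grid."""
    return CovariateLayer(grid=layer.grid.coarsen(factor),
                          values=aggregate_mean(layer.values, factor),
                          name=layer.name, units=layer.units)
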