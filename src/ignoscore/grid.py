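"""Regular analysis grids and the rasters defined on them.

All rasters share one memory convention: a ``(n_rows, n_cols)`` array whose
row 0 is the *southernmost* row (y increases with row index).  File writers
that need north-up ordering (ESRI ASCII) flip on the way out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class GridConfigError(ValueError):
    """Invalid grid geometry or grid-level configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular rectangular grid in projected metre coordinates.

    Cell membership is half-open, ``[low, high)`` on both axes; a point on
    the global maximum edge is assigned to the last row/column so the grid's
    closed bounding box is fully covered.

    Parameters
    ----------
    x_min, y_min
        Coordinates of the grid origin (south-west corner), metres.
    cell_size
        Cell edge length in metres (cells are square). The analyses here
        default to 10 km cells.
    n_rows, n_cols
        Grid dimensions; row 0 is the southernmost row.
    crs_label
        Free-text label of the projected CRS; never interpreted.
    """

    x_min: float
    y_min: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_min) and math.isfinite(self.y_min)):
            raise GridConfigError("grid origin must be finite")
        if not (self.cell_size > 0 and math.isfinite(self.cell_size)):
            raise GridConfigError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridConfigError(f"grid must have at least one cell, got {self.n_rows}x{self.n_cols}")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_index(self, x: float, y: float) -> tuple[int, int] | None:
        """Return ``(row, col)`` of the cell containing (x, y), or None.

        Half-open convention: a point on a shared interior edge belongs to
        the cell on its high side; points on the global max edge snap to the
        last cell.
        """
        if not (self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max):
            return None
        col = int((x - self.x_min) // self.cell_size)
        row = int((y - self.y_min) // self.cell_size)
        # global max edge belongs to the last cell
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return row, col

    def cell_indices(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised :meth:`cell_index`.

        Returns ``(rows, cols, in_bounds)`` where rows/cols are only valid
        where ``in_bounds`` is True.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inb = (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)
        col = np.floor_divide(x - self.x_min, self.cell_size).astype(int)
        row = np.floor_divide(y - self.y_min, self.cell_size).astype(int)
        np.clip(col, 0, self.n_cols - 1, out=col)
        np.clip(row, 0, self.n_rows - 1, out=row)
        return row, col, inb

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays ``(xc, yc)`` of shape ``(n_rows, n_cols)`` of cell centres."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xc, yc = np.meshgrid(xs, ys)
        return xc, yc

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid of the same extent with cells ``factor`` times larger.

        Trailing partial blocks still produce a (partial-coverage) coarse cell,
        matching block-mean aggregation of rasters.
        """
        if factor < 1:
            raise GridConfigError(f"aggregation factor must be >= 1, got {factor}")
        return GridSpec(
            x_min=self.x_min,
            y_min=self.y_min,
            cell_size=self.cell_size * factor,
            n_rows=-(-self.n_rows // factor),
            n_cols=-(-self.n_cols // factor),
            crs_label=self.crs_label,
        )


def _check_shape(grid: GridSpec, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{what} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class CountRaster:
    """Per-cell observation counts N_i for one taxon."""

    grid: GridSpec
    counts: np.ndarray
    taxon: str = ""
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.counts = _check_shape(self.grid, self.counts, "counts").astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("observation counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class IgnoranceRaster:
    """Per-cell half-ignorance scores I_i in (0, 1] for one taxon and one O_0.5."""

    grid: GridSpec
    scores: np.ndarray
    o_half: float
    taxon: str = ""

    def __post_init__(self) -> None:
        self.scores = _check_shape(self.grid, self.scores, "scores").astype(float)
        if self.o_half <= 0:
            raise ValueError(f"o_half must be positive, got {self.o_half}")
        if not ((self.scores > 0) & (self.scores <= 1)).all():
            raise ValueError("ignorance scores must lie in (0, 1]")


@dataclass
class CovariateLayer:
    """One gridded geographic variable; NaN marks cells outside the study mask."""

    grid: GridSpec
    values: np.ndarray
    name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = _check_shape(self.grid, self.values, "values").astype(float)
        if np.isinf(self.values).any():
            raise ValueError(f"covariate layer {self.name!r} contains infinite values")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)
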