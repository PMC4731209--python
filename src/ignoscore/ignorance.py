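"""Half-ignorance scores: from raw observation records to gridded uncertainty.

The half-ignorance algorithm maps a cell's record count N of a reference
taxonomic group to

    I = O_0.5 / (N + O_0.5),

where O_0.5 is the number of observations considered enough to halve the
ignorance: a never-visited cell scores 1 (absolute ignorance), a cell with
N = O_0.5 records scores 0.5, and I → 0 as effort accumulates.  With
O_0.5 = 1, a single record means the absence of further reports is read as
50% true absence / 50% undetected.  Because the right O_0.5 is taxon- and
study-dependent, analyses sweep it over a wide range (default 1–50).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ignoscore.grid import CountRaster, GridConfigError, GridSpec, IgnoranceRaster

logger = logging.getLogger(__name__)

#: O_0.5 sweep used throughout: 1, 2, 5, 10, 20, 50 observations.
DEFAULT_O_HALF: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


@dataclass(frozen=True)
class ObservationRecord:
    """One presence-only report: taxon label, projected x/y (m), year."""

    taxon: str
    x: float
    y: float
    year: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"record coordinates must be finite, got ({self.x}, {self.y})")


def count_observations(
    records: Iterable[ObservationRecord],
    grid: GridSpec,
    taxon: str = "",
) -> CountRaster:
    """Grid observation records into per-cell counts N_i.

    Each in-bounds record increments exactly one cell under the grid's
    half-open cell convention.  Records falling outside the grid are dropped,
    counted on the returned raster (``n_out_of_bounds``) and logged — never
    fatal, since ad hoc observation data routinely strays off the study area.
    """
    if not isinstance(grid, GridSpec):
        raise GridConfigError("count_observations requires a valid GridSpec")
    records = list(records)
    counts = np.zeros(grid.shape, dtype=np.int64)
    if records:
        x = np.array([r.x for r in records])
        y = np.array([r.y for r in records])
        rows, cols, inb = grid.cell_indices(x, y)
        np.add.at(counts, (rows[inb], cols[inb]), 1)
    n_oob = len(records) - int(counts.sum())
    if n_oob:
        logger.warning("%d of %d records fell outside the grid and were dropped", n_oob, len(records))
    return CountRaster(grid=grid, counts=counts, taxon=taxon, n_out_of_bounds=n_oob)


def half_ignorance(counts: CountRaster, o_half: float) -> IgnoranceRaster:
    """Apply the half-ignorance algorithm I_i = O_0.5 / (N_i + O_0.5).

    Scores lie in (0, 1]; a cell scores exactly 1 iff it holds no records,
    and 0.5 when it holds exactly O_0.5 records.
    """
    if not o_half > 0:
        raise ValueError(f"o_half must be positive, got {o_half}")
    scores = o_half / (counts.counts + o_half)
    return IgnoranceRaster(grid=counts.grid, scores=scores, o_half=float(o_half), taxon=counts.taxon)


def o_half_sweep(
    counts: CountRaster,
    o_half_values: Sequence[float] = DEFAULT_O_HALF,
) -> list[IgnoranceRaster]:
    """One ignorance raster per O_0.5 value, on the shared grid."""
    values = list(o_half_values)
    if not values:
        raise GridConfigError("o_half_values must not be empty")
    if any(v <= 0 for v in values):
        raise ValueError(f"all o_half values must be positive, got {values}")
    return [half_ignorance(counts, v) for v in values]


def counts_from_ignorance(scores: IgnoranceRaster) -> np.ndarray:
    """Invert the half-ignorance formula: N = O_0.5 (1 - I) / I."""
    return scores.o_half * (1.0 - scores.scores) / scores.scores
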