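"""Geometric covariate engineering: slope, aggregation, line and population density."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import LineString, box

from ignoscore.covariates import (
    LineFeatureSet,
    PopulationPolygonSet,
    aggregate_mean,
    line_density,
    log_density,
    population_density,
    slope_percent,
)
from ignoscore.grid import CovariateLayer, GridConfigError, GridSpec


def plane_dem(gx: float, gy: float, shape=(8, 10), cell=50.0) -> np.ndarray:
    """DEM of the plane z = gx*x + gy*y sampled at cell centres."""
    rows, cols = np.indices(shape)
    return gx * cols * cell + gy * rows * cell


class TestSlope:
    def test_flat_surface_has_zero_slope(self):
        assert (slope_percent(np.full((5, 5), 123.0), 50.0) == 0).all()

    @pytest.mark.parametrize("gx,gy,expected", [
        (0.1, 0.0, 10.0),
        (0.0, 0.1, 10.0),
        (0.3, 0.4, 50.0),
        (-0.3, 0.4, 50.0),
    ])
    def test_planar_dem_matches_analytic_gradient(self, gx, gy, expected):
        """Horn's estimate is exact for planes on all interior cells."""
        for cell in (10.0, 50.0):
            out = slope_percent(plane_dem(gx, gy, cell=cell), cell)
            np.testing.assert_allclose(out[1:-1, 1:-1], expected, atol=1e-9)

    def test_raster_smaller_than_3x3_is_domain_error(self):
        with pytest.raises(ValueError):
            slope_percent(np.zeros((2, 5)), 50.0)

    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_planar_slope_property(self, gx, gy):
        out = slope_percent(plane_dem(gx, gy), 50.0)
        np.testing.assert_allclose(out[1:-1, 1:-1], 100.0 * np.hypot(gx, gy), atol=1e-9)


class TestAggregateMean:
    def test_constant_raster_unchanged(self):
        out = aggregate_mean(np.full((4, 6), 3.5), 2)
        np.testing.assert_array_equal(out, np.full((2, 3), 3.5))

    def test_block_mean(self):
        out = aggregate_mean(np.array([[0.0, 0.0], [2.0, 2.0]]), 2)
        assert out.shape == (1, 1)
        assert out[0, 0] == 1.0

    def test_nodata_cells_ignored_in_mean(self):
        block = np.array([[1.0, np.nan], [3.0, np.nan]])
        assert aggregate_mean(block, 2)[0, 0] == 2.0

    def test_all_nodata_block_stays_nodata(self):
        assert np.isnan(aggregate_mean(np.full((2, 2), np.nan), 2)[0, 0])

    def test_partial_trailing_blocks_use_available_cells(self):
        fine = np.arange(6.0).reshape(2, 3)  # 3 cols, factor 2 -> one partial col
        out = aggregate_mean(fine, 2)
        assert out.shape == (1, 2)
        assert out[0, 0] == np.mean([0, 1, 3, 4])
        assert out[0, 1] == np.mean([2, 5])

    def test_bad_factor_is_configuration_error(self):
        with pytest.raises(GridConfigError):
            aggregate_mean(np.zeros((4, 4)), 0)

    @given(st.floats(-5, 5), st.floats(-100, 100))
    def test_commutes_with_affine_rescaling(self, a, b):
        rng = np.random.default_rng(99)
        fine = rng.normal(0, 1, (6, 6))
        lhs = aggregate_mean(a * fine + b, 3)
        rhs = a * aggregate_mean(fine, 3) + b
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestLineDensity:
    def test_no_lines_gives_zero_everywhere(self, small_grid):
        out = line_density(LineFeatureSet([], "road"), small_grid)
        assert (out.values == 0).all()
        assert out.units == "km/km²"

    def test_full_horizontal_crossing(self, small_grid):
        """10 km of road in a 100 km² cell is 0.1 km/km²."""
        line = LineString([(0, 5_000), (10_000, 5_000)])
        out = line_density(LineFeatureSet([line], "road"), small_grid)
        assert out.values[0, 0] == pytest.approx(0.1, abs=1e-12)
        assert out.values[0, 1:].sum() == 0

    def test_corner_to_corner_diagonal(self, small_grid):
        line = LineString([(0, 0), (10_000, 10_000)])
        out = line_density(LineFeatureSet([line], "road"), small_grid)
        assert out.values[0, 0] == pytest.approx(np.sqrt(2) * 0.1, rel=1e-12)

    def test_additive_over_feature_sets(self, small_grid, rng):
        pts = rng.uniform(0, 50_000, (6, 4))
        lines = [LineString([(r[0], r[1]), (r[2], r[3])]) for r in pts]
        combined = line_density(LineFeatureSet(lines, "road"), small_grid).values
        parts = sum(line_density(LineFeatureSet([l], "road"), small_grid).values for l in lines)
        np.testing.assert_allclose(combined, parts, atol=1e-12)

    def test_invariant_to_vertex_subdivision(self, small_grid):
        coarse = LineString([(1_000, 1_000), (41_000, 31_000)])
        t = np.linspace(0, 1, 17)
        dense = LineString(np.column_stack([1_000 + t * 40_000, 1_000 + t * 30_000]))
        a = line_density(LineFeatureSet([coarse], "road"), small_grid).values
        b = line_density(LineFeatureSet([dense], "road"), small_grid).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            LineFeatureSet([LineString()])


class TestPopulationDensity:
    def test_uniform_polygon_covering_grid(self, small_grid):
        poly = box(0, 0, 50_000, 50_000)  # 2500 km², population 5000
        out = population_density(PopulationPolygonSet([poly], [5000.0]), small_grid)
        np.testing.assert_allclose(out.values, 2.0, rtol=1e-12)  # people/km²

    def test_half_cell_polygon_gives_half_density(self, small_grid):
        # covers exactly half of cell (0,0); polygon density d = 1000 people/km²
        poly = box(0, 0, 5_000, 10_000)
        count = 1000.0 * 50.0  # d * polygon area in km²
        out = population_density(PopulationPolygonSet([poly], [count]), small_grid)
        assert out.values[0, 0] == pytest.approx(500.0, rel=1e-12)
        assert out.values[1:, :].sum() == 0

    def test_no_polygons_gives_zero(self, small_grid):
        out = population_density(PopulationPolygonSet([], []), small_grid)
        assert (out.values == 0).all()

    def test_zero_area_polygon_skipped_with_warning(self, small_grid, caplog):
        degenerate = box(0, 0, 0, 0)
        out = population_density(PopulationPolygonSet([degenerate], [100.0]), small_grid)
        assert (out.values == 0).all()

    def test_total_population_conserved(self, small_grid, rng):
        """sum(cell density x cell area) equals the polygon counts when all
        polygons lie inside the grid."""
        polys, counts = [], []
        for _ in range(8):
            x0, y0 = rng.uniform(0, 30_000, 2)
            polys.append(box(x0, y0, x0 + rng.uniform(2_000, 15_000), y0 + rng.uniform(2_000, 15_000)))
            counts.append(float(rng.uniform(10, 10_000)))
        out = population_density(PopulationPolygonSet(polys, counts), small_grid)
        total = (out.values * small_grid.cell_area_km2).sum()
        assert total == pytest.approx(sum(counts), rel=1e-6)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            PopulationPolygonSet([box(0, 0, 1, 1)], [-5.0])


class TestLogDensity:
    def layer(self, values, grid=None):
        arr = np.asarray(values, dtype=float)
        grid = grid or GridSpec(0, 0, 10_000.0, *arr.shape)
        return CovariateLayer(grid, arr, "population_density", "people/km²")

    def test_zero_with_unit_offset(self):
        out = log_density(self.layer([[0.0]]), offset=1.0)
        assert out.values[0, 0] == 0.0

    def test_ln_e(self):
        out = log_density(self.layer([[np.e - 1.0]]), offset=1.0)
        assert out.values[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_order_preserved(self, rng):
        vals = rng.uniform(0, 1000, (4, 4))
        out = log_density(self.layer(vals), offset=0.5)
        assert np.array_equal(np.argsort(vals, axis=None), np.argsort(out.values, axis=None))

    def test_default_offset_is_smallest_positive_value(self):
        out = log_density(self.layer([[0.0, 2.0, 8.0]]))
        assert out.values[0, 0] == pytest.approx(np.log(2.0))

    def test_nonpositive_offset_is_configuration_error(self):
        with pytest.raises(GridConfigError):
            log_density(self.layer([[1.0]]), offset=0.0)
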