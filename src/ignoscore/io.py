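"""File formats, run configuration and the end-to-end pipeline.

Formats are deliberately plain: delimited CSV for records and tidy tables,
ESRI ASCII grid for rasters (human-readable, round-trips exactly at the
printed precision), GeoJSON for line and polygon features.  Every run writes
a manifest recording the configuration hash, package version and produced
artefacts, and all randomness flows from the single seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ignoscore import __version__
from ignoscore.beta_glm import MCMCSettings, PosteriorFit, boundary_adjust, fit_covariate_models
from ignoscore.grid import CountRaster, CovariateLayer, GridSpec, IgnoranceRaster
from ignoscore.ignorance import DEFAULT_O_HALF, ObservationRecord, count_observations, o_half_sweep
from ignoscore.synthetic import SyntheticScenario, simulate_scenario
from ignoscore.thresholds import threshold_report

logger = logging.getLogger(__name__)

NODATA_DEFAULT = -9999.0


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# observation records


def read_observations(
    path: str | Path,
    year_window: tuple[int, int] = (2000, 2014),
) -> tuple[list[ObservationRecord], dict]:
    """Read observation records from CSV (columns: taxon, x, y, year).

    Rows outside the inclusive year window are excluded and counted;
    malformed rows (non-numeric coordinates or year) are routed to a rejects
    table instead of aborting the run.  Returns ``(records, report)`` where
    the report carries n_total / n_year_filtered / n_rejected and the rejects
    themselves.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["taxon", "x", "y", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    bad = x.isna() | y.isna() | year.isna() | np.isinf(x.fillna(0)) | np.isinf(y.fillna(0))
    rejects = df[bad].copy()
    ok = df[~bad]
    x, y, year = x[~bad], y[~bad], year[~bad].astype(int)

    lo, hi = year_window
    in_window = (year >= lo) & (year <= hi)
    n_year_filtered = int((~in_window).sum())
    records = [
        ObservationRecord(str(t), float(xi), float(yi), int(yr))
        for t, xi, yi, yr in zip(ok["taxon"][in_window], x[in_window], y[in_window], year[in_window])
    ]
    report = {
        "n_total": int(len(df)),
        "n_rejected": int(bad.sum()),
        "n_year_filtered": n_year_filtered,
        "n_accepted": len(records),
        "rejects": rejects,
    }
    if report["n_rejected"]:
        logger.warning("%d malformed rows routed to rejects", report["n_rejected"])
    if n_year_filtered:
        logger.info("%d records outside year window %s excluded", n_year_filtered, year_window)
    return records, report


# ---------------------------------------------------------------------------
# ESRI ASCII grid rasters


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float = NODATA_DEFAULT,
) -> None:
    """Write a raster as an ESRI ASCII grid (north-up row order on disk)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in out[::-1]:  # internal row 0 is southernmost; file is north-up
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an ESRI ASCII grid; returns ``(values, grid, nodata)`` with NaN no-data."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"ESRI ASCII grid {path} missing header field {req}")
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(f"data block shape {values.shape} contradicts header in {path}")
    values = values[::-1]  # back to south-up internal order
    values[values == nodata] = np.nan
    grid = GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"],
                    int(header["nrows"]), int(header["ncols"]))
    return values, grid, nodata


# ---------------------------------------------------------------------------
# GeoJSON vector features


def read_line_features(path: str | Path, classes: list[str] | None = None):
    """Read polylines from GeoJSON; optional filter on the ``class`` property.

    Class filtering is how source-specific rules (e.g. excluding forestry
    access roads, keeping footpaths and hiking trails) are expressed.
    """
    from shapely.geometry import shape

    from ignoscore.covariates import LineFeatureSet

    with open(path) as fh:
        gj = json.load(fh)
    lines = []
    label = classes[0] if classes else "line"
    for feat in gj.get("features", []):
        cls = (feat.get("properties") or {}).get("class", "")
        if classes is not None and cls not in classes:
            continue
        geom = shape(feat["geometry"])
        if geom.geom_type == "LineString":
            lines.append(geom)
        elif geom.geom_type == "MultiLineString":
            lines.extend(list(geom.geoms))
    return LineFeatureSet(lines=lines, feature_class=label)


def read_population_polygons(path: str | Path):
    """Read polygons with a ``population`` property from GeoJSON."""
    from shapely.geometry import shape

    from ignoscore.covariates import PopulationPolygonSet

    with open(path) as fh:
        gj = json.load(fh)
    polys, counts = [], []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "population" not in props:
            raise FormatError("population polygon feature missing 'population' property")
        polys.append(shape(feat["geometry"]))
        counts.append(float(props["population"]))
    return PopulationPolygonSet(polygons=polys, counts=counts)


# ---------------------------------------------------------------------------
# tidy tables


def layer_to_tidy(layer: CovariateLayer) -> pd.DataFrame:
    """Cell-wise long format: cell_id (row-major from the south-west), name, value."""
    vals = layer.values.reshape(-1)
    return pd.DataFrame({
        "cell_id": np.arange(vals.size),
        "name": layer.name,
        "value": vals,
    })


def fit_summary_frame(fits: list[PosteriorFit]) -> pd.DataFrame:
    frames = []
    for fit in fits:
        s = fit.summary()
        s.insert(0, "taxon", fit.taxon)
        s.insert(1, "covariate", fit.model.covariate_name)
        s.insert(2, "o_half", fit.o_half)
        s.insert(3, "degree", fit.model.degree)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; see the packaged example YAML."""

    out_dir: str = "results/run"
    seed: int = 0
    o_half_values: tuple[float, ...] = DEFAULT_O_HALF
    year_window: tuple[int, int] = (2000, 2014)
    # either a synthetic scenario...
    scenario: SyntheticScenario | None = None
    # ...or real inputs
    records_path: str | None = None
    covariate_paths: dict[str, str] = field(default_factory=dict)
    grid: GridSpec | None = None
    # model settings
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    standardize: bool = True
    boundary_mode: str = "squeeze"   # "squeeze" | "drop"
    fit_covariates: tuple[str, ...] | None = None   # None = all layers
    threshold_target: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "grid" in kwargs and kwargs["grid"] is not None:
            kwargs["grid"] = GridSpec(**kwargs["grid"])
        if "scenario" in kwargs and kwargs["scenario"] is not None:
            sc = dict(kwargs["scenario"])
            if "grid" in sc:
                sc["grid"] = GridSpec(**sc["grid"])
            kwargs["scenario"] = SyntheticScenario(**sc)
        if "mcmc" in kwargs and kwargs["mcmc"] is not None:
            kwargs["mcmc"] = MCMCSettings(**kwargs["mcmc"])
        for tup in ("o_half_values", "year_window", "fit_covariates"):
            if tup in kwargs and kwargs[tup] is not None:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = json.dumps(self, default=lambda o: getattr(o, "__dict__", str(o)),
                           sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis: counts → ignorance sweep → fits → thresholds.

    Deterministic given the config seed.  Writes, under ``config.out_dir``:
    one ignorance raster per O_0.5 value, covariate rasters and a tidy CSV,
    a per-parameter fit summary, a model-comparison table, the threshold
    table, and a JSON manifest (config hash, version, artefact list, record
    accounting).  Returns the result bundle in memory as well.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "artefacts": [],
        "accounting": {},
    }

    def _write_raster(name: str, values: np.ndarray, grid: GridSpec) -> None:
        path = out / name
        write_ascii_grid(path, values, grid)
        manifest["artefacts"].append(name)

    # --- stage 1: counts -------------------------------------------------
    if config.scenario is not None:
        layers, counts = simulate_scenario(config.scenario.with_(seed=config.seed))
        taxon = config.scenario.taxon
    else:
        if config.records_path is None or config.grid is None:
            raise ValueError("config needs either a scenario or records_path + grid")
        records, report = read_observations(config.records_path, config.year_window)
        manifest["accounting"].update({k: v for k, v in report.items() if k != "rejects"})
        taxon = records[0].taxon if records else ""
        counts = count_observations(records, config.grid, taxon=taxon)
        manifest["accounting"]["n_out_of_bounds"] = counts.n_out_of_bounds
        manifest["accounting"]["n_gridded"] = counts.total
        layers = {}
        for name, p in config.covariate_paths.items():
            values, grid, _ = read_ascii_grid(p)
            layers[name] = CovariateLayer(grid, values, name)
    manifest["accounting"]["total_count"] = counts.total
    _write_raster("counts.asc", counts.counts.astype(float), counts.grid)

    # --- stage 2: ignorance sweep ----------------------------------------
    rasters = o_half_sweep(counts, config.o_half_values)
    for r in rasters:
        _write_raster(f"ignorance_{taxon or 'taxon'}_o{r.o_half:g}.asc", r.scores, r.grid)

    tidy = pd.concat([layer_to_tidy(l) for l in layers.values()], ignore_index=True)
    tidy.to_csv(out / "covariates.csv", index=False)
    manifest["artefacts"].append("covariates.csv")
    for layer in layers.values():
        _write_raster(f"covariate_{layer.name}.asc", layer.values, layer.grid)

    # --- stage 3: regressions --------------------------------------------
    fit_names = config.fit_covariates or tuple(layers)
    all_fits: list[PosteriorFit] = []
    chosen_fits: list[PosteriorFit] = []
    comparison_rows = []
    for o_i, raster in enumerate(rasters):
        y_raw = raster.scores.reshape(-1)
        for c_i, name in enumerate(fit_names):
            x = layers[name].values.reshape(-1)
            valid = np.isfinite(x) & np.isfinite(y_raw)
            if config.boundary_mode == "drop":
                valid &= y_raw < 1.0       # ignorance is in (0,1], so dropping 1s leaves (0,1)
                y = y_raw[valid]
            else:
                y = boundary_adjust(y_raw[valid])
            fits, selection = fit_covariate_models(
                y, x[valid],
                MCMCSettings(iterations=config.mcmc.iterations, burn_in=config.mcmc.burn_in,
                             chains=config.mcmc.chains,
                             seed=config.seed + 101 * o_i + 10 * c_i,
                             adapt_interval=config.mcmc.adapt_interval),
                covariate_name=name, standardize=config.standardize,
                taxon=taxon, o_half=raster.o_half,
            )
            all_fits.extend(fits.values())
            chosen_fits.append(selection.chosen)
            for comp in selection.comparisons:
                comparison_rows.append({
                    "taxon": taxon, "covariate": name, "o_half": raster.o_half,
                    "reduced_degree": comp.reduced.degree, "full_degree": comp.full.degree,
                    "delta_deviance": comp.delta_deviance, "improves": comp.improves,
                    "r_squared_full": comp.r_squared_full,
                    "chosen_degree": selection.chosen_degree,
                })

    fit_summary_frame(all_fits).to_csv(out / "fit_summary.csv", index=False, float_format="%.10g")
    manifest["artefacts"].append("fit_summary.csv")
    pd.DataFrame(comparison_rows).to_csv(out / "model_comparisons.csv", index=False, float_format="%.10g")
    manifest["artefacts"].append("model_comparisons.csv")

    # --- stage 4: thresholds ---------------------------------------------
    thresholds = threshold_report(
        [f for f in chosen_fits if f.model.degree > 0], target=config.threshold_target)
    thresholds.to_csv(out / "thresholds.csv", index=False, float_format="%.10g")
    manifest["artefacts"].append("thresholds.csv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "counts": counts, "layers": layers, "ignorance": rasters,
        "fits": all_fits, "chosen": chosen_fits,
        "comparisons": pd.DataFrame(comparison_rows),
        "thresholds": thresholds, "manifest": manifest,
    }
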