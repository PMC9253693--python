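"""End-to-end orchestration: scene → mask → composite → fit → maps → tables.

`run_pipeline` chains the individual stages; each stage is an ordinary
function so the numbered analysis drivers (and tests) can run them
independently.  Given the same configuration and seed the pipeline is
deterministic down to the bytes of its summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import agb as agb_mod
from . import climate as climate_mod
from . import compositing
from . import trends as trends_mod
from .agb import CalibratedModel, SampleSite, read_sites_csv
from .climate import StationRecord, read_stations_csv
from .errors import ConfigurationError, StageError
from .raster import AnnualStack, Raster, read_mask_ascii, read_ascii_grid, write_ascii_grid
from .synthetic import SceneConfig, SyntheticScene, generate_scene, _config_to_jsonable

logger = logging.getLogger(__name__)

#: (variable, period) pairs that get full per-pixel correlation maps;
#: the table itself covers all 4 × 13 combinations via regional series
MAP_PAIRS = (("precip", "annual"), ("tmean", "annual"), ("precip", 1), ("tmean", 7))

ALL_PERIODS: tuple = ("annual",) + tuple(range(1, 13))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``scene`` (synthetic route) or ``input_paths`` (file
    route with keys mask_epoch1, mask_epoch2, ndvi_dir, stations, sites)
    must be given.
    """

    out_dir: str | Path
    scene: SceneConfig | None = None
    input_paths: dict[str, str] | None = None
    years: Sequence[int] | None = None
    lat_threshold: float = 47.0
    lat_of_origin: float | None = None
    seed: int = 0
    write_rasters: bool = False
    raster_dir: str | Path | None = None

    def validate(self) -> None:
        if (self.scene is None) == (self.input_paths is None):
            raise ConfigurationError(
                "scene/input_paths", "exactly one input route must be provided")
        years = self.years or (self.scene.years if self.scene else None)
        if years is not None and len(years) < 3:
            raise ConfigurationError("years", "at least 3 analysis years required")


@dataclass
class RunReport:
    summary: dict
    paths: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_inputs(config: RunConfig) -> tuple[Raster, Raster, dict[int, list[Raster]],
                                            list[StationRecord], list[SampleSite],
                                            float]:
    """Simulate or read the four inputs; returns lat_of_origin as well."""
    if config.scene is not None:
        scene_cfg = config.scene
        if scene_cfg.seed != config.seed:
            from dataclasses import replace
            scene_cfg = replace(scene_cfg, seed=config.seed)
        scene = generate_scene(scene_cfg)
        comps = {y: scene.composites_for_year(y) for y in scene_cfg.years}
        lat0 = scene_cfg.effective_lat_of_origin
        return (scene.mask_epoch1, scene.mask_epoch2, comps,
                scene.stations, scene.sites, lat0)
    paths = config.input_paths
    mask1 = read_mask_ascii(paths["mask_epoch1"])
    mask2 = read_mask_ascii(paths["mask_epoch2"])
    comps: dict[int, list[Raster]] = {}
    for f in sorted(Path(paths["ndvi_dir"]).glob("ndvi_*.asc")):
        _, year_s, _ = f.stem.split("_")
        comps.setdefault(int(year_s), []).append(read_ascii_grid(f))
    if config.years:
        comps = {y: comps[y] for y in config.years}
    stations = read_stations_csv(paths["stations"])
    sites = read_sites_csv(paths["sites"])
    lat0 = config.lat_of_origin if config.lat_of_origin is not None else 48.2
    return mask1, mask2, comps, stations, sites, lat0


def calibrate(sites: Sequence[SampleSite], stack: AnnualStack
              ) -> tuple[CalibratedModel, list[tuple[float, float]]]:
    """Pair each site with its own year's NDVI_max and fit/select the model."""
    pairs = []
    for s in sites:
        ndvi = compositing.site_ndvi_max(stack, s.x, s.y, s.year)
        if np.isfinite(ndvi) and ndvi > 0:
            pairs.append((ndvi, s.agb_density))
        else:
            logger.warning("site %s has no usable NDVI_max; dropped", s.site_id)
    models = agb_mod.fit_candidates(pairs)
    best = agb_mod.select_best(models)
    return best, pairs


def predict_agb_stack(model: CalibratedModel, ndvi_stack: AnnualStack,
                      mask: Raster) -> AnnualStack:
    layers = [agb_mod.predict_raster(model, ndvi_stack.layer(y), mask)
              for y in ndvi_stack.years]
    return AnnualStack.from_layers(ndvi_stack.years, layers)


def climate_stacks(stations: Sequence[StationRecord], grid, years: Sequence[int],
                   variables=climate_mod.VARIABLES, periods=ALL_PERIODS,
                   ) -> dict[tuple[str, int | str], AnnualStack]:
    """Kriged per-year climate surfaces for every (variable, period)."""
    out = {}
    for var in variables:
        for period in periods:
            layers = [
                climate_mod.krige_station_period(stations, grid, y, period, var).surface
                for y in years
            ]
            out[(var, period)] = AnnualStack.from_layers(years, layers)
    return out


def _hash_config(config: RunConfig) -> str:
    d = {
        "scene": _config_to_jsonable(config.scene) if config.scene else None,
        "input_paths": config.input_paths,
        "years": list(config.years) if config.years else None,
        "lat_threshold": config.lat_threshold,
        "seed": config.seed,
    }
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _table_to_dict(tbl: trends_mod.CorrelationTable) -> dict:
    stars = tbl.stars()
    return {
        "r": {row: {c: (None if np.isnan(tbl.r.loc[row, c]) else round(float(tbl.r.loc[row, c]), 6))
                    for c in tbl.r.columns} for row in tbl.r.index},
        "significance": {row: {c: stars.loc[row, c] for c in tbl.r.columns}
                         for row in tbl.r.index},
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write the machine-readable summary.

    Outputs: stable mask and (optionally) raster stacks, fitted model JSON,
    correlation table CSV, and ``summary.json`` holding the model, the
    regional carbon summary, the regional trend, and all table cells.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raster_dir = Path(config.raster_dir) if config.raster_dir else out_dir / "rasters"
    paths: dict[str, str] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    with stage("inputs"):
        mask1, mask2, comps, stations, sites, lat0 = load_inputs(config)

    with stage("mask"):
        stable = compositing.stable_marsh_mask(mask1, mask2)

    with stage("composite"):
        ndvi_stack = compositing.annual_max_stack(comps)
        years = list(ndvi_stack.years)

    with stage("fit"):
        model, pairs = calibrate(sites, ndvi_stack)
        model.to_json(out_dir / "model.json")
        paths["model"] = str(out_dir / "model.json")

    with stage("predict"):
        agb_stack = predict_agb_stack(model, ndvi_stack, stable)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN outside mask
            mean_agb = Raster(agb_stack.grid,
                              np.nanmean(agb_stack.values, axis=0))
        summary_region = agb_mod.regional_summary(mean_agb, stable)
        agb_series = trends_mod.regional_series(agb_stack, stable)

    with stage("trend"):
        trend_map = trends_mod.pixelwise_map(agb_stack, None, stable, "trend")
        regional_slope = trends_mod.theta_slope(agb_series.to_numpy())
        regional_p = trends_mod.slope_significance(agb_series.to_numpy())
        finite_slopes = trend_map.values.values[np.isfinite(trend_map.values.values)]

    with stage("correlate"):
        cstacks = climate_stacks(stations, ndvi_stack.grid, years)
        clim_series = {k: trends_mod.regional_series(st, stable)
                       for k, st in cstacks.items()}
        table = trends_mod.correlation_table(agb_series, clim_series)
        table.to_csv(out_dir / "correlation_table.csv")
        paths["correlation_table"] = str(out_dir / "correlation_table.csv")
        corr_maps = {
            f"{var}-{period}": trends_mod.pixelwise_map(
                agb_stack, cstacks[(var, period)], stable, "correlation",
                variable=f"{var}-{period}")
            for var, period in MAP_PAIRS
        }

    with stage("latitude_split"):
        lat = ndvi_stack.grid.latitude_raster(lat0)
        try:
            split = trends_mod.latitude_split(agb_stack, cstacks, stable, lat,
                                              config.lat_threshold)
            split_out = {k: _table_to_dict(v) for k, v in split.items()}
        except Exception as exc:
            logger.warning("latitude split unavailable: %s", exc)
            split_out = {"error": str(exc)}

    if config.write_rasters:
        with stage("write_rasters"):
            raster_dir.mkdir(parents=True, exist_ok=True)
            from .raster import write_mask_ascii

            write_mask_ascii(stable, raster_dir / "stable_mask.asc")
            for y in years:
                write_ascii_grid(ndvi_stack.layer(y),
                                 raster_dir / f"ndvi_max_{y}.asc", fmt="%.4f")
                write_ascii_grid(agb_stack.layer(y),
                                 raster_dir / f"agb_{y}.asc", fmt="%.2f")
            trends_mod.write_statmap_ascii(trend_map,
                                           raster_dir / "agb_trend.asc",
                                           raster_dir / "agb_trend_p.asc")
            for name, sm in corr_maps.items():
                trends_mod.write_statmap_ascii(
                    sm, raster_dir / f"corr_{name}.asc",
                    raster_dir / f"corr_{name}_p.asc")
            paths["raster_dir"] = str(raster_dir)

    summary = {
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "years": years,
        "n_sites_used": len(pairs),
        "model": {
            "form": model.form, "a": model.a, "b": model.b,
            "r_squared": model.r_squared, "rmse": model.rmse,
            "relative_error_pct": model.relative_error_pct,
        },
        "regional": {
            "mean_density_gC_m2": summary_region.mean_density,
            "area_m2": summary_region.area_m2,
            "total_TgC": summary_region.total_TgC,
        },
        "trend": {
            "regional_slope_gC_m2_a": float(regional_slope),
            "regional_p": float(regional_p),
            "map_median_slope": float(np.median(finite_slopes)) if finite_slopes.size else None,
            "pct_pixels_significant": float(np.mean(
                trend_map.p_values.values[np.isfinite(trend_map.p_values.values)] < 0.05
            ) * 100.0) if finite_slopes.size else None,
        },
        "correlation_table": _table_to_dict(table),
        "latitude_split": split_out,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["summary"] = str(summary_path)

    manifest = {"config_hash": summary["config_hash"], "timings_s": timings,
                "outputs": sorted(paths)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = str(out_dir / "manifest.json")
    return RunReport(summary=summary, paths=paths)
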