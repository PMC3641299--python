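"""Configuration-driven orchestration of the two-stage analysis.

Stage graph (acyclic): synth -> preprocess -> trend -> model -> risk;
factors depends on synth only and feeds model/risk; report collects
everything.  Every run writes its resolved configuration, seed and per-stage
wall times into a manifest so paper-gap parameters are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import factors as fm
from . import model as dm
from . import preprocess as pp
from . import synthetic as syn
from . import trend as tr
from .geodata import (Grid, ZoneGrid, rasterize_features, read_features,
                      read_points_csv, read_raster, write_raster)
from .kriging import fit_spherical_variogram, krige_spherical

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("degrisk")

STAGES = ("synth", "preprocess", "trend", "factors", "model", "risk", "report")


@dataclass
class PipelineConfig:
    """All paths and module parameters of one pipeline run."""

    scenario_dir: str = "scenario"
    out_dir: str = "out"
    seed: int = 0

    # smoother
    flag_weights: dict = field(default_factory=lambda: dict(pp.DEFAULT_FLAG_WEIGHTS))
    half_window: int = 4
    poly_order: int = 2
    envelope_iters: int = 2
    weight_decay: float = 0.5
    season_start: tuple = (4, 1)
    season_end: tuple = (10, 31)

    # trend classification
    p_high: float = 0.05
    p_medium: float = 0.10

    # kriging
    variogram_lags: int = 15
    kriging_neighborhood: int = 16

    # sampling / model
    block: int = 3
    vif_threshold: float = 5.0
    alpha_remove: float = 0.05
    pcp_threshold: float = 0.5

    # lulc flags
    lulc_min_years: int = 6

    # scenario generation (synth stage)
    scenario_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.season_start = tuple(cfg.season_start)
        cfg.season_end = tuple(cfg.season_end)
        cfg.flag_weights = {int(k): float(v) for k, v in cfg.flag_weights.items()}
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_start"] = list(self.season_start)
        d["season_end"] = list(self.season_end)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing artifact {path!r}: run the {stage!r} stage first")
    return path


def run_pipeline(config: PipelineConfig, stages=STAGES, overwrite: bool = False) -> dict:
    """Execute the requested stages in dependency order; return the run manifest."""
    stages = [s for s in STAGES if s in set(stages)]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "config_hash": config.config_hash(),
                      "stages": {}, "artifacts": {}}
    for stage in stages:
        t0 = time.perf_counter()
        log.info("stage %s ...", stage)
        arts = _STAGE_FUNCS[stage](config, overwrite)
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3)}
        manifest["artifacts"].update(arts)
        log.info("stage %s done in %.2fs", stage, dt)
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage_synth(config: PipelineConfig, overwrite: bool) -> dict:
    cfg = syn.ScenarioConfig(seed=config.seed, **config.scenario_overrides)
    syn.make_scenario(cfg, config.scenario_dir, overwrite=overwrite)
    return {"scenario": config.scenario_dir}


def _stage_preprocess(config: PipelineConfig, overwrite: bool) -> dict:
    cube_dir = _require(os.path.join(config.scenario_dir, "cube"), "synth")
    cube = pp.read_cube(cube_dir)
    screened = pp.screen_quality(cube, config.flag_weights)
    filled, unusable = pp.fill_cube_gaps(screened)
    filled.values = pp.savgol_adaptive_cube(
        np.nan_to_num(filled.values), filled.weights,
        half_window=config.half_window, poly_order=config.poly_order,
        envelope_iters=config.envelope_iters, weight_decay=config.weight_decay)
    filled.values[:, unusable] = np.nan
    years = sorted(set(pd.DatetimeIndex(cube.dates).year))
    window = pp.SeasonWindow(config.season_start, config.season_end)
    sums = pp.seasonal_sum(filled, window, years, unusable=unusable)
    out = os.path.join(config.out_dir, "sums")
    pp.write_sum_stack(sums, out)
    return {"sums": out}


def _stage_trend(config: PipelineConfig, overwrite: bool) -> dict:
    sums = pp.read_sum_stack(_require(os.path.join(config.out_dir, "sums"), "preprocess"))
    thresholds = tr.TrendClassThresholds(config.p_high, config.p_medium)
    result = tr.fit_pixel_trend(sums)
    class_map = tr.classify_trend(result, thresholds)
    degraded = tr.binarize_degraded(class_map)
    endpoint = tr.endpoint_sensitivity(sums, thresholds)
    zones = ZoneGrid(**vars(read_raster(
        _require(os.path.join(config.scenario_dir, "zones.tif"), "synth"))))
    areal = tr.zonal_area_stats(class_map, zones)
    arts = {}
    for name, grid in (("slope", result.slope), ("trend_p", result.p_two_sided),
                       ("class_map", class_map), ("degraded", degraded)):
        path = os.path.join(config.out_dir, f"{name}.tif")
        write_raster(grid, path)
        arts[name] = path
    areal_path = os.path.join(config.out_dir, "areal_stats.csv")
    areal.to_csv(areal_path, index=False)
    ep_path = os.path.join(config.out_dir, "endpoint_sensitivity.json")
    with open(ep_path, "w") as fh:
        json.dump(endpoint, fh, indent=2)
    arts.update({"areal_stats": areal_path, "endpoint_sensitivity": ep_path})
    return arts


def _stage_factors(config: PipelineConfig, overwrite: bool) -> dict:
    sdir = config.scenario_dir
    _require(os.path.join(sdir, "zones.tif"), "synth")
    zones = ZoneGrid(**vars(read_raster(os.path.join(sdir, "zones.tif"))))
    spec = zones.spec

    def geoms(name: str):
        return [g for _, g in read_features(os.path.join(sdir, f"{name}.geojson"))]

    canals, collectors, roads = geoms("canals"), geoms("collectors"), geoms("roads")
    pumps, settlements, water = geoms("pumps"), geoms("settlements"), geoms("water_bodies")

    # groundwater surfaces by ordinary kriging of the well sets
    layers: dict[str, Grid] = {}
    for key, fname in (("gw_table", "wells_gw_table.csv"),
                       ("gw_salinity", "wells_gw_salinity.csv")):
        wells = read_points_csv(os.path.join(sdir, fname))
        model = fit_spherical_variogram(wells, n_lags=config.variogram_lags)
        layers[key] = krige_spherical(wells, model, spec,
                                      neighborhood=config.kriging_neighborhood)

    lulc_dir = os.path.join(sdir, "lulc")
    table = pd.read_csv(os.path.join(lulc_dir, "years.csv"))
    lvals = np.stack([read_raster(os.path.join(lulc_dir, p)).values.astype(int)
                      for p in table["path"]])
    lulc = fm.LULCSeries(spec, table["year"].to_numpy(), lvals)
    no_change, uncult = fm.lulc_flags(lulc, min_years=config.lulc_min_years)

    wu = pd.read_csv(os.path.join(sdir, "water_use.csv"))
    series_cols = [c for c in wu.columns if c != "district"]
    water_use = {int(r["district"]): [r[c] for c in series_cols] for _, r in wu.iterrows()}

    layers.update({
        "landuse_change": no_change,
        "uncultivated": uncult,
        "canal_density": fm.line_density(canals, spec),
        "collector_density": fm.line_density(collectors, spec),
        "water_use_delta": fm.district_layer(zones, water_use),
        "slope_pct": read_raster(os.path.join(sdir, "slope.tif")),
        "dist_canals": fm.euclidean_distance(rasterize_features(canals, spec)),
        "dist_collectors": fm.euclidean_distance(rasterize_features(collectors, spec)),
        "dist_pumps": fm.euclidean_distance(rasterize_features(pumps, spec)),
        "dist_roads": fm.euclidean_distance(rasterize_features(roads, spec)),
        "dist_settlements": fm.euclidean_distance(rasterize_features(settlements, spec)),
        "dist_water": fm.euclidean_distance(rasterize_features(water, spec)),
    })
    bonitation = read_raster(os.path.join(sdir, "bonitation.tif"))
    stack = fm.assemble_factor_stack(layers, bonitation=bonitation)
    out = os.path.join(config.out_dir, "factors")
    fm.write_factor_stack(stack, out)
    return {"factors": out}


def _load_stack(config: PipelineConfig) -> fm.FactorStack:
    return fm.read_factor_stack(_require(os.path.join(config.out_dir, "factors"),
                                         "factors"))


def _stage_model(config: PipelineConfig, overwrite: bool) -> dict:
    degraded = read_raster(_require(os.path.join(config.out_dir, "degraded.tif"), "trend"))
    stack = _load_stack(config)
    table = dm.block_sample(degraded, stack, block=config.block, seed=config.seed)
    table = dm.split_calibration(table, seed=config.seed + 1)
    cal = table[table["split"] == "calibration"]
    val = table[table["split"] == "validation"]
    retained, vif_table = dm.vif_screen(cal, predictors=stack.names,
                                        threshold=config.vif_threshold)
    full = dm.fit_logistic(cal, retained)
    stepwise = dm.backward_stepwise(cal, retained, alpha_remove=config.alpha_remove)
    comparison = dm.compare_auc(full, stepwise, val)
    final = full if comparison.recommended == "a" else stepwise
    report = dm.validate_fit(final, val, threshold=config.pcp_threshold)

    out = config.out_dir
    table.to_csv(os.path.join(out, "sample.csv"), index=False)
    vif_table.to_csv(os.path.join(out, "vif.csv"), index=False)
    dm.fit_report(full).to_csv(os.path.join(out, "model_full.csv"), index=False)
    dm.fit_report(stepwise).to_csv(os.path.join(out, "model_stepwise.csv"), index=False)
    with open(os.path.join(out, "validation.json"), "w") as fh:
        json.dump({"final_model": "full" if final is full else "stepwise",
                   "comparison": dataclasses.asdict(comparison),
                   "validation": report.to_dict(), "seed": config.seed}, fh, indent=2)
    with open(os.path.join(out, "final_fit.json"), "w") as fh:
        json.dump({"predictors": final.predictors,
                   "params": {k: float(v) for k, v in final.params.items()}},
                  fh, indent=2)
    return {"sample": os.path.join(out, "sample.csv"),
            "vif": os.path.join(out, "vif.csv"),
            "model_full": os.path.join(out, "model_full.csv"),
            "model_stepwise": os.path.join(out, "model_stepwise.csv"),
            "validation": os.path.join(out, "validation.json"),
            "final_fit": os.path.join(out, "final_fit.json")}


def _stage_risk(config: PipelineConfig, overwrite: bool) -> dict:
    fit_path = _require(os.path.join(config.out_dir, "final_fit.json"), "model")
    with open(fit_path) as fh:
        doc = json.load(fh)
    params = pd.Series(doc["params"])
    fit = dm.LogisticFit(predictors=doc["predictors"], params=params,
                         bse=params * np.nan, zvalues=params * np.nan,
                         pvalues=params * np.nan, cov=pd.DataFrame(),
                         llf=np.nan, llnull=np.nan, n=0)
    stack = _load_stack(config)
    risk = dm.risk_deciles(fit, stack)
    cpath = os.path.join(config.out_dir, "risk_classes.tif")
    ppath = os.path.join(config.out_dir, "risk_probability.tif")
    write_raster(risk.classes, cpath)
    write_raster(risk.probability, ppath)
    return {"risk_classes": cpath, "risk_probability": ppath}


def _stage_report(config: PipelineConfig, overwrite: bool) -> dict:
    return {}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "preprocess": _stage_preprocess,
    "trend": _stage_trend,
    "factors": _stage_factors,
    "model": _stage_model,
    "risk": _stage_risk,
    "report": _stage_report,
}
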