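"""Synthetic study region with known ground truth.

Generates a complete artificial irrigated-lowland scenario so that every
pipeline stage can be exercised end to end without external data:

* spatially autocorrelated factor fields (groundwater table depth 0.8–2.5 m,
  salinity 0.5–4 g/l, terrain slope 0–3 %), built by Gaussian-smoothing
  seeded white noise and rescaling;
* infrastructure vectors (canals, collectors, roads as polylines; pumps as
  points; settlements and water bodies as polygons) from which distance and
  density layers are derived with the factor-map operations;
* a soil-fertility (bonitation) class grid from a quantile cut of a smooth
  fertility field, and rectangular districts with annual water-use series;
* an annual land-use series embedding persistent, rotating and abandoned
  (fallow) areas, so the change/abandonment flags are derivable;
* well samples of the groundwater surfaces (for the kriging stage);
* a binary degradation outcome drawn cell-wise from the logistic model with
  known coefficients (defaults: intercept −3.55 and the five headline
  effects 1.46 groundwater table, 0.71 uncultivated, 0.40 bonitation I,
  0.25 slope, 0.23 groundwater salinity);
* an 11-year cube of 16-day NDVI composites in which degraded cells carry a
  planted linear decline of seasonal ΣNDVI and all cells carry observation
  noise and quality-flagged/missing observations.

The seasonal NDVI template is a quadratic bump spanning the growing season,
chosen so that an order-2 Savitzky–Golay fit reproduces in-season values
exactly: at zero noise the planted ΣNDVI slopes survive the full
pre-processing chain to machine precision, which pins down the stage-1
closed loop.  The degradation labels and the NDVI declines are coupled
(degraded cells decline), so stage 1's output can serve as stage 2's
dependent variable exactly as in a real campaign.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, box

from .factors import (FactorStack, LULCSeries, assemble_factor_stack,
                      district_layer, euclidean_distance, line_density,
                      lulc_flags, write_factor_stack)
from .geodata import (Grid, GridSpec, ZoneGrid, rasterize_features,
                      write_features, write_raster)
from .preprocess import NDVICube, SeasonWindow, write_cube

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "Scenario",
    "DEFAULT_TRUE_BETA",
    "smooth_field",
    "make_factor_fields",
    "make_degradation_labels",
    "make_ndvi_cube",
    "make_wells",
    "generate_scenario",
    "make_scenario",
]

#: default generating coefficients of the degradation outcome
DEFAULT_TRUE_BETA: dict[str, float] = {
    "const": -3.55,
    "gw_table": 1.46,
    "uncultivated": 0.71,
    "bonitation_1": 0.40,
    "slope_pct": 0.25,
    "gw_salinity": 0.23,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition parameters of the artificial region."""

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 250.0
    crs_label: str = "synthetic-utm"
    first_year: int = 2000
    n_years: int = 11
    composites_per_year: int = 23
    season: SeasonWindow = field(default_factory=SeasonWindow)
    slope_range: tuple[float, float] = (-0.4, -0.1)   # planted ΣNDVI decline per year
    base_amplitude: float = 0.7                        # seasonal NDVI bump height
    ndvi_baseline: float = 0.12                        # off-season NDVI level
    noise_sigma: float = 0.02                          # per-observation NDVI noise
    low_quality_rate: float = 0.15                     # flag 1 (half weight)
    missing_rate: float = 0.05                         # flags 2/3 (dropped)
    blur_radius: float = 6.0                           # field smoothness, cells
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    n_wells: int = 500
    well_noise_sigma: float = 0.0
    uncultivated_fraction: float = 0.15
    rotation_fraction: float = 0.20
    n_districts_rows: int = 2
    n_districts_cols: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 3 or self.composites_per_year < 5:
            raise ValueError("need >= 3 years and >= 5 composites per year")
        for r in (self.low_quality_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0,
                        self.n_rows * self.cell_size, self.cell_size, self.crs_label)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)


@dataclass
class ScenarioTruth:
    """Ground truth stored alongside the generated data."""

    beta: dict[str, float]
    slope: Grid                 # planted ΣNDVI slope per year
    degraded: Grid              # Bernoulli outcome of the logistic model
    prevalence: float
    gw_table_surface: Grid
    gw_salinity_surface: Grid


@dataclass
class Scenario:
    """In-memory scenario: all pipeline inputs plus the truth."""

    cfg: ScenarioConfig
    cube: NDVICube
    stack: FactorStack
    zones: ZoneGrid
    lulc: LULCSeries
    wells_gw_table: pd.DataFrame
    wells_gw_salinity: pd.DataFrame
    water_use: dict[int, list[float]]
    vectors: dict[str, list]
    bonitation: Grid
    truth: ScenarioTruth


def smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                 radius: float, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Gaussian-smoothed white noise, min-max rescaled to [lo, hi]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), radius, mode="reflect")
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def _random_polylines(rng: np.random.Generator, spec: GridSpec, n: int,
                      mean_length_cells: float = 60.0) -> list[LineString]:
    """Random gently bent polylines across the region (canal/road style)."""
    w = spec.n_cols * spec.cell_size
    h = spec.n_rows * spec.cell_size
    lines = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, w), rng.uniform(spec.origin_y - h, spec.origin_y)
        ang = rng.uniform(0, 2 * np.pi)
        pts = [(x0, y0)]
        for _ in range(3):
            step = rng.uniform(0.5, 1.5) * mean_length_cells / 3 * spec.cell_size
            ang += rng.normal(0, 0.3)
            x0, y0 = x0 + step * np.cos(ang), y0 + step * np.sin(ang)
            pts.append((x0, y0))
        lines.append(LineString(pts))
    return lines


def _district_zones(cfg: ScenarioConfig) -> ZoneGrid:
    spec = cfg.spec
    values = np.zeros(spec.shape)
    ri = np.linspace(0, spec.n_rows, cfg.n_districts_rows + 1).astype(int)
    ci = np.linspace(0, spec.n_cols, cfg.n_districts_cols + 1).astype(int)
    zid = 1
    for a in range(cfg.n_districts_rows):
        for b in range(cfg.n_districts_cols):
            values[ri[a]:ri[a + 1], ci[b]:ci[b + 1]] = zid
            zid += 1
    return ZoneGrid(spec, values)


def _make_lulc(cfg: ScenarioConfig, rng: np.random.Generator
               ) -> tuple[LULCSeries, np.ndarray]:
    """Annual land-use series embedding persistent, rotating and fallow areas."""
    spec = cfg.spec
    n_years = max(9, 6)
    years = np.arange(cfg.first_year + 1, cfg.first_year + 1 + n_years)
    base = np.digitize(smooth_field(rng, spec.shape, cfg.blur_radius),
                       [0.25, 0.5, 0.75]) + 1  # crop classes 1..4
    uncult_f = smooth_field(rng, spec.shape, cfg.blur_radius)
    uncult = uncult_f > np.quantile(uncult_f, 1.0 - cfg.uncultivated_fraction)
    rot_f = smooth_field(rng, spec.shape, cfg.blur_radius)
    rotate = (~uncult) & (rot_f > np.quantile(rot_f, 1.0 - cfg.rotation_fraction))
    layers = np.empty((n_years,) + spec.shape, dtype=int)
    for k in range(n_years):
        lay = base.copy()
        lay[rotate] = (base[rotate] + k // 2) % 4 + 1  # class switch every 2 years
        lay[uncult] = 0                                # fallow code
        layers[k] = lay
    return LULCSeries(spec, years, layers, fallow_codes=(0,)), uncult


def make_wells(surface: Grid, n: int, noise_sigma: float,
               rng: np.random.Generator) -> pd.DataFrame:
    """Sample n well locations uniformly over the unmasked extent.

    The well value is the surface value of the containing cell plus Gaussian
    noise with sd *noise_sigma*.
    """
    if n < 1:
        raise ValueError("need n >= 1 wells")
    spec = surface.spec
    valid = np.argwhere(~surface.nodata_mask)
    pick = valid[rng.integers(len(valid), size=n)]
    # jitter within the cell so locations are generic points
    x = spec.origin_x + (pick[:, 1] + rng.uniform(0.05, 0.95, n)) * spec.cell_size
    y = spec.origin_y - (pick[:, 0] + rng.uniform(0.05, 0.95, n)) * spec.cell_size
    vals = surface.values[pick[:, 0], pick[:, 1]] + rng.normal(0, noise_sigma, n)
    return pd.DataFrame({"x": x, "y": y, "value": vals})


def make_factor_fields(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Build the full predictor stack plus the vector/table inputs behind it.

    Returns (stack, zones, lulc, water_use, vectors, truth_fields) where
    truth_fields holds the noise-free groundwater surfaces.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    spec = cfg.spec

    gw_table = Grid(spec, smooth_field(rng, spec.shape, cfg.blur_radius, 0.8, 2.5))
    gw_salinity = Grid(spec, smooth_field(rng, spec.shape, cfg.blur_radius, 0.5, 4.0))
    slope_pct = Grid(spec, smooth_field(rng, spec.shape, cfg.blur_radius, 0.0, 3.0))
    fertility = smooth_field(rng, spec.shape, cfg.blur_radius)
    bon = np.digitize(fertility, np.quantile(fertility, [0.10, 0.40, 0.80])) + 1
    bonitation = Grid(spec, bon.astype(float))

    canals = _random_polylines(rng, spec, 14)
    collectors = _random_polylines(rng, spec, 8)
    roads = _random_polylines(rng, spec, 10)
    w = spec.n_cols * spec.cell_size
    h = spec.n_rows * spec.cell_size
    pumps = [Point(rng.uniform(0, w), rng.uniform(spec.origin_y - h, spec.origin_y))
             for _ in range(12)]
    settlements = []
    for _ in range(6):
        cx, cy = rng.uniform(0, w), rng.uniform(spec.origin_y - h, spec.origin_y)
        s = rng.uniform(2, 5) * spec.cell_size
        settlements.append(box(cx, cy, cx + s, cy + s))
    water_bodies = []
    for _ in range(4):
        cx, cy = rng.uniform(0, w), rng.uniform(spec.origin_y - h, spec.origin_y)
        s = rng.uniform(3, 8) * spec.cell_size
        water_bodies.append(box(cx, cy, cx + 1.5 * s, cy + s))
    vectors = {"canals": canals, "collectors": collectors, "roads": roads,
               "pumps": pumps, "settlements": settlements, "water_bodies": water_bodies}

    zones = _district_zones(cfg)
    water_use = {}
    for z in zones.zone_ids():
        base_use = rng.uniform(80, 160)
        water_use[int(z)] = list(base_use + np.cumsum(rng.normal(0, 8, cfg.n_years)))

    lulc, _ = _make_lulc(cfg, rng)
    no_change, uncultivated = lulc_flags(lulc)

    layers = {
        "landuse_change": no_change,
        "uncultivated": uncultivated,
        "canal_density": line_density(canals, spec),
        "collector_density": line_density(collectors, spec),
        "water_use_delta": district_layer(zones, water_use),
        "slope_pct": slope_pct,
        "gw_table": gw_table,
        "gw_salinity": gw_salinity,
        "dist_canals": euclidean_distance(rasterize_features(canals, spec)),
        "dist_collectors": euclidean_distance(rasterize_features(collectors, spec)),
        "dist_pumps": euclidean_distance(rasterize_features(pumps, spec)),
        "dist_roads": euclidean_distance(rasterize_features(roads, spec)),
        "dist_settlements": euclidean_distance(rasterize_features(settlements, spec)),
        "dist_water": euclidean_distance(rasterize_features(water_bodies, spec)),
    }
    stack = assemble_factor_stack(layers, bonitation=bonitation)
    truth_fields = {"gw_table": gw_table.copy(), "gw_salinity": gw_salinity.copy(),
                    "bonitation": bonitation}
    return stack, zones, lulc, water_use, vectors, truth_fields


def make_degradation_labels(stack: FactorStack, beta: dict[str, float],
                            rng: np.random.Generator) -> tuple[Grid, float]:
    """Draw the binary outcome cell-wise from the logistic model with known beta."""
    eta = np.full(stack.spec.shape, beta.get("const", 0.0), dtype=float)
    for name, b in beta.items():
        if name == "const":
            continue
        eta += b * stack.values(name)
    p = 1.0 / (1.0 + np.exp(-eta))
    labels = (rng.random(stack.spec.shape) < p).astype(float)
    grid = Grid(stack.spec, labels, stack.mask.copy())
    prevalence = float(labels[~stack.mask].mean()) if (~stack.mask).any() else 0.0
    return grid, prevalence


def _composite_dates(cfg: ScenarioConfig) -> np.ndarray:
    """Fixed calendar composite start dates: the same 23 month/day slots each year.

    Slots are the 16-day positions of a 365-day year, so season membership is
    identical across years (leap years shift a slot by one calendar day at
    most, never across the season boundary).
    """
    base = pd.date_range("2001-01-01", periods=cfg.composites_per_year, freq="16D")
    slots = [(d.month, d.day) for d in base]
    dates = []
    for y in cfg.years:
        for m, d in slots:
            dates.append(np.datetime64(f"{y:04d}-{m:02d}-{d:02d}"))
    return np.array(dates, dtype="datetime64[D]")


def make_ndvi_cube(cfg: ScenarioConfig, degraded: Grid,
                   rng: np.random.Generator | None = None
                   ) -> tuple[NDVICube, Grid]:
    """Generate the composite cube with planted ΣNDVI declines on degraded cells.

    Returns (cube, true per-year ΣNDVI slope grid).  The seasonal template is
    quadratic across the window of every in-season composite, so order-2
    smoothing reproduces in-season values and the planted slope is exact.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    spec = cfg.spec
    dates = _composite_dates(cfg)
    npy = cfg.composites_per_year
    T = len(dates)

    i = np.arange(npy, dtype=float)
    center, half = 12.0, 10.0
    q = 1.0 - ((i - center) / half) ** 2
    q = np.maximum(q, 0.0)
    in_season = cfg.season.contains(dates[:npy])
    q_sum = float(q[in_season].sum())
    n_in = int(in_season.sum())

    slopes = np.zeros(spec.shape)
    deg = degraded.values == 1
    slopes[deg] = rng.uniform(cfg.slope_range[0], cfg.slope_range[1], int(deg.sum()))
    true_slope = Grid(spec, slopes, degraded.nodata_mask.copy())

    # amplitude per year so that seasonal-sum slope equals the planted slope
    y_idx = np.arange(cfg.n_years, dtype=float)
    amp = cfg.base_amplitude + (slopes[None, :, :] * y_idx[:, None, None]) / q_sum

    values = np.empty((T,) + spec.shape, dtype=float)
    for yk in range(cfg.n_years):
        block = cfg.ndvi_baseline + amp[yk][None, :, :] * q[:, None, None]
        values[yk * npy:(yk + 1) * npy] = block
    if cfg.noise_sigma > 0:
        values += rng.normal(0.0, cfg.noise_sigma, values.shape)
    np.clip(values, -1.0, 1.0, out=values)

    u = rng.random(values.shape)
    quality = np.zeros(values.shape, dtype=int)
    quality[u < cfg.missing_rate + cfg.low_quality_rate] = 1
    quality[u < cfg.missing_rate] = 3
    return NDVICube(spec, dates, values, quality), true_slope


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the full scenario in memory (deterministic in cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    stack, zones, lulc, water_use, vectors, truth_fields = make_factor_fields(cfg, rng)
    beta = dict(cfg.true_beta)
    degraded, prevalence = make_degradation_labels(stack, beta, rng)
    cube, true_slope = make_ndvi_cube(cfg, degraded, rng)
    wells_t = make_wells(truth_fields["gw_table"], cfg.n_wells, cfg.well_noise_sigma, rng)
    wells_s = make_wells(truth_fields["gw_salinity"], cfg.n_wells, cfg.well_noise_sigma, rng)
    truth = ScenarioTruth(beta=beta, slope=true_slope, degraded=degraded,
                          prevalence=prevalence,
                          gw_table_surface=truth_fields["gw_table"],
                          gw_salinity_surface=truth_fields["gw_salinity"])
    return Scenario(cfg=cfg, cube=cube, stack=stack, zones=zones, lulc=lulc,
                    wells_gw_table=wells_t, wells_gw_salinity=wells_s,
                    water_use=water_use, vectors=vectors,
                    bonitation=truth_fields["bonitation"], truth=truth)


def make_scenario(cfg: ScenarioConfig, outdir: str | os.PathLike,
                  overwrite: bool = False) -> Scenario:
    """Generate a scenario and write every pipeline input + truth to disk."""
    outdir = str(outdir)
    manifest_path = os.path.join(outdir, "manifest.json")
    if os.path.exists(manifest_path) and not overwrite:
        raise FileExistsError(f"{outdir} already holds a scenario; pass overwrite=True")
    os.makedirs(outdir, exist_ok=True)
    sc = generate_scenario(cfg)

    write_cube(sc.cube, os.path.join(outdir, "cube"))
    write_factor_stack(sc.stack, os.path.join(outdir, "factors_truth"))
    write_raster(sc.zones, os.path.join(outdir, "zones.tif"))
    lulc_dir = os.path.join(outdir, "lulc")
    os.makedirs(lulc_dir, exist_ok=True)
    lrows = []
    for k, year in enumerate(sc.lulc.years):
        p = f"lulc_{int(year)}.tif"
        write_raster(Grid(sc.lulc.spec, sc.lulc.values[k].astype(float), sc.lulc.mask),
                     os.path.join(lulc_dir, p))
        lrows.append({"year": int(year), "path": p})
    pd.DataFrame(lrows).to_csv(os.path.join(lulc_dir, "years.csv"), index=False)

    sc.wells_gw_table.to_csv(os.path.join(outdir, "wells_gw_table.csv"), index=False)
    sc.wells_gw_salinity.to_csv(os.path.join(outdir, "wells_gw_salinity.csv"), index=False)
    pd.DataFrame([{"district": z, **{f"y{k}": v for k, v in enumerate(series)}}
                  for z, series in sc.water_use.items()]
                 ).to_csv(os.path.join(outdir, "water_use.csv"), index=False)
    for name, geoms in sc.vectors.items():
        write_features([({"id": k}, g) for k, g in enumerate(geoms)],
                       os.path.join(outdir, f"{name}.geojson"))

    # ready-made input rasters consumed by the factor stage
    write_raster(sc.stack.layer("slope_pct"), os.path.join(outdir, "slope.tif"))
    write_raster(sc.bonitation, os.path.join(outdir, "bonitation.tif"))

    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    write_raster(sc.truth.slope, os.path.join(truth_dir, "true_slope.tif"))
    write_raster(sc.truth.degraded, os.path.join(truth_dir, "degraded.tif"))
    write_raster(sc.truth.gw_table_surface, os.path.join(truth_dir, "gw_table.tif"))
    write_raster(sc.truth.gw_salinity_surface, os.path.join(truth_dir, "gw_salinity.tif"))

    cfg_echo = dataclasses.asdict(cfg)
    cfg_echo["season"] = {"start": list(cfg.season.start), "end": list(cfg.season.end)}
    with open(manifest_path, "w") as fh:
        json.dump({"seed": cfg.seed, "config": cfg_echo, "beta": sc.truth.beta,
                   "prevalence": sc.truth.prevalence,
                   "paths": {"cube": "cube", "factors_truth": "factors_truth",
                             "zones": "zones.tif", "lulc": "lulc",
                             "wells_gw_table": "wells_gw_table.csv",
                             "wells_gw_salinity": "wells_gw_salinity.csv",
                             "water_use": "water_use.csv", "truth": "truth"}},
                  fh, indent=2)
    return sc
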