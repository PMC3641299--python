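"""Construction of the predictor layers for the spatial risk model.

The degradation model regresses the binary degraded-land outcome on a set
of aligned raster predictors: land-use change and abandonment flags derived
from an annual land-use series, soil-fertility (bonitation) class dummies,
canal/collector densities, a district-level water-use variability surface,
terrain slope, kriged groundwater table depth and salinity, and Euclidean
distances to infrastructure (canals, collectors, pumps, roads, settlements,
water bodies).  :func:`assemble_factor_stack` gathers them into an ordered
:class:`FactorStack` with per-layer kind tags (binary / continuous) and a
combined validity mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata import Grid, GridSpec, ZoneGrid, read_raster, validate_stack, write_raster

__all__ = [
    "FACTOR_ORDER",
    "FACTOR_KINDS",
    "FactorStack",
    "LULCSeries",
    "euclidean_distance",
    "line_density",
    "lulc_flags",
    "district_layer",
    "bonitation_dummies",
    "assemble_factor_stack",
    "write_factor_stack",
    "read_factor_stack",
]

#: canonical layer order of the predictor stack
FACTOR_ORDER = [
    "landuse_change",     # 1 = same agricultural use persisted, 0 = changed
    "uncultivated",       # 1 = abandoned from cropping
    "bonitation_1",       # soil fertility class I "very high"
    "bonitation_2",       # class II "increased"
    "bonitation_3",       # class III "average"
    "bonitation_4",       # class IV "low"
    "canal_density",      # m/m^2
    "collector_density",  # m/m^2
    "water_use_delta",    # mean |consecutive-year difference| of district water use
    "slope_pct",          # terrain slope, %
    "gw_table",           # groundwater table depth, m
    "gw_salinity",        # groundwater salinity, g/l
    "dist_canals",        # Euclidean distances, m
    "dist_collectors",
    "dist_pumps",
    "dist_roads",
    "dist_settlements",
    "dist_water",
]

FACTOR_KINDS = {name: ("binary" if name in
                       ("landuse_change", "uncultivated", "bonitation_1",
                        "bonitation_2", "bonitation_3", "bonitation_4")
                       else "continuous")
                for name in FACTOR_ORDER}


@dataclass
class FactorStack:
    """Ordered, aligned, named predictor layers with a combined validity mask."""

    spec: GridSpec
    names: list[str]
    layers: dict[str, Grid]
    kinds: dict[str, str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
            for g in self.layers.values():
                self.mask |= g.nodata_mask

    def layer(self, name: str) -> Grid:
        if name not in self.layers:
            raise KeyError(f"factor stack has no layer {name!r}")
        return self.layers[name]

    def values(self, name: str) -> np.ndarray:
        return self.layer(name).values

    def frame_at(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Tabulate every layer at the given cell indices."""
        data = {"row": rows, "col": cols}
        for name in self.names:
            data[name] = self.layers[name].values[rows, cols]
        return pd.DataFrame(data)


@dataclass
class LULCSeries:
    """Annual land-use/land-cover class grids with a designated fallow code set."""

    spec: GridSpec
    years: np.ndarray
    values: np.ndarray  # (n_years, rows, cols) integer class codes
    fallow_codes: tuple[int, ...] = (0,)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values)
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        if self.values.shape != (len(self.years),) + self.spec.shape:
            raise ValueError("LULC layers must be (n_years, n_rows, n_cols)")


def euclidean_distance(targets: Grid) -> Grid:
    """Center-to-center distance (m) from every cell to the nearest target cell.

    *targets* is a presence grid (1 = target).  Target cells map to 0.
    """
    presence = targets.values == 1
    if not presence.any():
        raise ValueError("euclidean_distance requires at least one target cell")
    cs = targets.spec.cell_size
    dist = ndimage.distance_transform_edt(~presence, sampling=(cs, cs))
    return Grid(targets.spec, dist.astype(float), targets.nodata_mask.copy())


def line_density(lines, spec: GridSpec) -> Grid:
    """Per-cell clipped polyline length divided by cell area (m/m²)."""
    values = np.zeros(spec.shape, dtype=float)
    from .geodata import _candidate_cells  # shared bbox -> cell-range helper

    for geom in lines:
        i0, i1, j0, j1 = _candidate_cells(geom, spec)
        if i1 < i0 or j1 < j0:
            continue
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                seg = geom.intersection(spec.cell_box(i, j))
                if not seg.is_empty:
                    values[i, j] += seg.length
    return Grid(spec, values / spec.cell_area)


def lulc_flags(series: LULCSeries, min_years: int = 6,
               uncultivated_consecutive: bool = False) -> tuple[Grid, Grid]:
    """Derive the land-use change and abandonment flags from an annual series.

    no-change = 1 where one identical land-use class persists for at least
    *min_years* consecutive years; uncultivated = 1 where the cell carries a
    fallow code for at least *min_years* years — in total by default,
    consecutively when *uncultivated_consecutive* is set.
    """
    n_years = len(series.years)
    if n_years < min_years:
        raise ValueError(f"series has {n_years} years; min_years={min_years}")
    vals = series.values
    run = np.ones(series.spec.shape)
    longest = np.ones(series.spec.shape)
    for k in range(1, n_years):
        same = vals[k] == vals[k - 1]
        run = np.where(same, run + 1, 1.0)
        longest = np.maximum(longest, run)
    no_change = (longest >= min_years).astype(float)

    fallow = np.isin(vals, series.fallow_codes)
    if uncultivated_consecutive:
        frun = np.zeros(series.spec.shape)
        flongest = np.zeros(series.spec.shape)
        for k in range(n_years):
            frun = np.where(fallow[k], frun + 1, 0.0)
            flongest = np.maximum(flongest, frun)
        uncult = (flongest >= min_years).astype(float)
    else:
        uncult = (fallow.sum(axis=0) >= min_years).astype(float)

    mask = series.mask.copy()
    return Grid(series.spec, no_change, mask), Grid(series.spec, uncult, mask.copy())


def mean_abs_delta(series) -> float:
    """Mean absolute consecutive-year difference of an annual series."""
    a = np.asarray(series, dtype=float)
    if a.size < 2:
        return 0.0
    return float(np.abs(np.diff(a)).mean())


def district_layer(zones: ZoneGrid, table: dict) -> Grid:
    """Spread per-district values onto the grid.

    Table values may be scalars or annual series; a series is reduced to its
    mean absolute consecutive-year difference (the water-use variability
    convention).  Raises on districts present in the grid but not the table.
    """
    ids = zones.zone_ids()
    missing = [int(z) for z in ids if z not in table]
    if missing:
        raise KeyError(f"districts missing from table: {missing}")
    reduced = {z: (float(v) if np.isscalar(v) else mean_abs_delta(v))
               for z, v in table.items()}
    values = np.zeros(zones.spec.shape, dtype=float)
    for z in ids:
        values[zones.values == z] = reduced[int(z)]
    return Grid(zones.spec, values, zones.nodata_mask.copy())


def bonitation_dummies(bonitation: Grid) -> dict[str, Grid]:
    """Expand a fertility class grid (codes 1–4) into four 0/1 dummy layers."""
    valid = ~bonitation.nodata_mask
    codes = bonitation.values[valid]
    if codes.size and not np.isin(codes, (1, 2, 3, 4)).all():
        raise ValueError("bonitation classes must be in {1, 2, 3, 4}")
    out = {}
    for c in (1, 2, 3, 4):
        out[f"bonitation_{c}"] = Grid(bonitation.spec,
                                      (bonitation.values == c).astype(float),
                                      bonitation.nodata_mask.copy())
    return out


def assemble_factor_stack(layers: dict[str, Grid], bonitation: Grid | None = None
                          ) -> FactorStack:
    """Assemble named predictor grids (plus a bonitation class grid) into a stack.

    Validates alignment, expands bonitation into the four dummy layers,
    checks that binary layers contain only {0, 1}, and unions the masks.
    """
    layers = dict(layers)
    if bonitation is not None:
        layers.update(bonitation_dummies(bonitation))
    unknown = sorted(set(layers) - set(FACTOR_ORDER))
    if unknown:
        raise ValueError(f"unknown factor layer names: {unknown}")
    names = [n for n in FACTOR_ORDER if n in layers]
    validate_stack([layers[n] for n in names]).raise_if_failed()
    for name in names:
        if FACTOR_KINDS[name] == "binary":
            g = layers[name]
            vals = g.values[~g.nodata_mask]
            if vals.size and not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError(f"binary layer {name!r} contains values outside {{0, 1}}")
    spec = layers[names[0]].spec
    return FactorStack(spec=spec, names=names,
                       layers={n: layers[n] for n in names},
                       kinds={n: FACTOR_KINDS[n] for n in names})


def write_factor_stack(stack: FactorStack, directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    rows = []
    for name in stack.names:
        path = f"{name}.tif"
        g = stack.layers[name]
        write_raster(Grid(g.spec, g.values, g.nodata_mask | stack.mask),
                     os.path.join(directory, path))
        rows.append({"name": name, "kind": stack.kinds[name], "path": path})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.csv"), index=False)


def read_factor_stack(directory: str | os.PathLike) -> FactorStack:
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    layers = {}
    kinds = {}
    for _, row in manifest.iterrows():
        layers[row["name"]] = read_raster(os.path.join(directory, row["path"]))
        kinds[row["name"]] = row["kind"]
    names = [n for n in FACTOR_ORDER if n in layers] + \
            [n for n in layers if n not in FACTOR_ORDER]
    spec = layers[names[0]].spec
    return FactorStack(spec=spec, names=names, layers=layers, kinds=kinds)
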