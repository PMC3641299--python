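"""Grid data model, alignment checks, and raster/vector/table I/O.

All spatial layers in the pipeline share a single carrier: a georeferenced
2D array (:class:`Grid`) with an explicit nodata mask.  Map coordinates are
metres, the origin is the top-left *corner* of the grid, rows increase
southward, and the center of cell (i, j) sits at
``(origin_x + (j + 0.5) * cell_size, origin_y - (i + 0.5) * cell_size)``.
All cell-to-cell distances are computed center-to-center.

Rasters are stored as single-band GeoTIFFs (pixel scale + tiepoint tags,
nodata declared in the GDAL_NODATA tag).  The CRS is carried as an opaque
label and compared for equality only; no reprojection is performed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import box, mapping, shape

__all__ = [
    "GridSpec",
    "Grid",
    "ZoneGrid",
    "StackReport",
    "read_raster",
    "write_raster",
    "validate_stack",
    "rasterize_features",
    "read_features",
    "write_features",
    "read_points_csv",
    "write_points_csv",
]

# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster layer: shape, top-left corner, square cell size."""

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center map coordinates, shape (n_rows, n_cols)."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        x = self.origin_x + (j + 0.5) * self.cell_size
        y = self.origin_y - (i + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_box(self, i: int, j: int):
        """Shapely rectangle of cell (i, j)."""
        x0 = self.origin_x + j * self.cell_size
        y1 = self.origin_y - i * self.cell_size
        return box(x0, y1 - self.cell_size, x0 + self.cell_size, y1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size


@dataclass
class Grid:
    """A single raster layer: values plus a boolean nodata mask (True = missing)."""

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must match values shape")

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def copy(self) -> "Grid":
        return Grid(self.spec, self.values.copy(), self.nodata_mask.copy())

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(self.spec, values, self.nodata_mask.copy() if mask is None else mask)


class ZoneGrid(Grid):
    """Grid whose unmasked values are integer zone identifiers >= 1 (e.g. districts)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values[~self.nodata_mask]
        if vals.size and (np.any(vals < 1) or np.any(vals != np.round(vals))):
            raise ValueError("zone ids must be integers >= 1 on unmasked cells")

    def zone_ids(self) -> np.ndarray:
        return np.unique(self.values[~self.nodata_mask]).astype(int)


def write_raster(grid: Grid, path: str | os.PathLike, nodata: float = DEFAULT_NODATA) -> None:
    """Write a Grid as a single-band float32 GeoTIFF; masked cells stored as *nodata*."""
    spec = grid.spec
    values = grid.values.astype(np.float64).copy()
    values[grid.nodata_mask] = nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(spec.cell_size), float(spec.cell_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(spec.origin_x), float(spec.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(
        path,
        values,
        extratags=extratags,
        description=json.dumps({"crs_label": spec.crs_label}),
    )


def read_raster(path: str | os.PathLike) -> Grid:
    """Read a single-band GeoTIFF into a Grid; the nodata value becomes the mask."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster, got shape {values.shape}")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing geotransform tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells ({sx} x {sy})")
        tie = tags[_TAG_TIEPOINT].value
        origin_x, origin_y = tie[3], tie[4]
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs_label = "local"
        if 270 in tags:
            try:
                crs_label = json.loads(tags[270].value).get("crs_label", "local")
            except (json.JSONDecodeError, AttributeError):
                crs_label = str(tags[270].value)
    spec = GridSpec(values.shape[0], values.shape[1], float(origin_x), float(origin_y),
                    float(sx), crs_label)
    if nodata is not None:
        mask = np.isclose(values, nodata) | ~np.isfinite(values)
    else:
        mask = ~np.isfinite(values)
    return Grid(spec, values, mask)


_SPEC_FIELDS = ("n_rows", "n_cols", "origin_x", "origin_y", "cell_size", "crs_label")


@dataclass
class StackReport:
    """Result of an alignment check: which GridSpec fields differ across layers."""

    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise ValueError(f"grids are not aligned; mismatching fields: {self.mismatches}")


def validate_stack(grids: list[Grid]) -> StackReport:
    """Check that every grid shares an identical GridSpec, field by field.

    Order-independent: the report lists the set of fields taking more than one
    distinct value across the stack.
    """
    if not grids:
        raise ValueError("validate_stack requires at least one grid")
    mismatches = []
    for f in _SPEC_FIELDS:
        vals = {getattr(g.spec, f) for g in grids}
        if len(vals) > 1:
            mismatches.append(f)
    return StackReport(mismatches=mismatches)


def rasterize_features(features, spec: GridSpec, mode: str = "presence") -> Grid:
    """Burn vector features onto a grid.

    mode="presence": 1 where a feature intersects the cell rectangle, else 0.
    mode="zone": features are (zone_id, polygon) pairs; each cell takes the id
    of the polygon covering its *center* (lowest id wins on overlap); cells
    covered by no polygon are masked.
    """
    if mode == "presence":
        values = np.zeros(spec.shape, dtype=float)
        for geom in features:
            _burn_presence(geom, spec, values)
        return Grid(spec, values)
    if mode == "zone":
        values = np.zeros(spec.shape, dtype=float)
        mask = np.ones(spec.shape, dtype=bool)
        for zone_id, geom in sorted(features, key=lambda t: -t[0]):
            _burn_zone(int(zone_id), geom, spec, values, mask)
        return ZoneGrid(spec, values, mask)
    raise ValueError(f"unknown rasterize mode: {mode!r}")


def _candidate_cells(geom, spec: GridSpec):
    """Index range of cells whose rectangles could touch geom's bounding box."""
    minx, miny, maxx, maxy = geom.bounds
    j0 = max(0, int(np.floor((minx - spec.origin_x) / spec.cell_size)))
    j1 = min(spec.n_cols - 1, int(np.floor((maxx - spec.origin_x) / spec.cell_size)))
    i0 = max(0, int(np.floor((spec.origin_y - maxy) / spec.cell_size)))
    i1 = min(spec.n_rows - 1, int(np.floor((spec.origin_y - miny) / spec.cell_size)))
    return i0, i1, j0, j1


def _burn_presence(geom, spec: GridSpec, values: np.ndarray) -> None:
    i0, i1, j0, j1 = _candidate_cells(geom, spec)
    if i1 < i0 or j1 < j0:
        return
    shapely.prepare(geom)
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            if geom.intersects(spec.cell_box(i, j)):
                values[i, j] = 1.0


def _burn_zone(zone_id: int, geom, spec: GridSpec, values: np.ndarray, mask: np.ndarray) -> None:
    i0, i1, j0, j1 = _candidate_cells(geom, spec)
    if i1 < i0 or j1 < j0:
        return
    for i in range(i0, i1 + 1):
        y = spec.origin_y - (i + 0.5) * spec.cell_size
        for j in range(j0, j1 + 1):
            x = spec.origin_x + (j + 0.5) * spec.cell_size
            if shapely.intersects_xy(geom, x, y):
                values[i, j] = zone_id
                mask[i, j] = False


# ---------------------------------------------------------------------------
# Vector and table I/O


def read_features(path: str | os.PathLike):
    """Read a GeoJSON FeatureCollection -> list of (properties, shapely geometry)."""
    with open(path) as fh:
        doc = json.load(fh)
    return [(feat.get("properties") or {}, shape(feat["geometry"])) for feat in doc["features"]]


def write_features(features, path: str | os.PathLike) -> None:
    """Write (properties, geometry) pairs as a GeoJSON FeatureCollection."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": props, "geometry": mapping(geom)}
            for props, geom in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_points_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a point table CSV with columns x, y, value."""
    df = pd.read_csv(path)
    missing = {"x", "y", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[["x", "y", "value"]].astype(float)


def write_points_csv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[["x", "y", "value"]].to_csv(path, index=False)
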