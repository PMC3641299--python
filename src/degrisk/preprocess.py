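"""Pre-processing of 16-day vegetation-index composite cubes.

The stage-1 chain mirrors standard practice for MODIS-style NDVI series:

1. quality screening — per-observation quality flags are mapped to fit
   weights; weight 0 marks the observation as missing;
2. gap filling — missing observations are replaced by linear interpolation
   in time (nearest-valid hold at the series ends, never extrapolation);
3. adaptive Savitzky–Golay smoothing — a weighted local polynomial fit with
   optional upper-envelope iterations in which points falling below the
   current fit are progressively down-weighted, so the smoothed curve tracks
   the upper envelope of the series (cloud and haze bias NDVI downward);
4. growing-season summation — smoothed values of composites whose *start
   date* falls inside the season window are summed per pixel and year,
   yielding one ΣNDVI layer per year.

The flag→weight defaults follow the MOD13Q1 pixel-reliability convention:
0 (good) → 1.0, 1 (marginal) → 0.5, 2 (snow/ice) and 3 (cloudy) → 0
(treated as missing).  Filled gap values re-enter the smoother at the
minimum positive weight so they steer the fit as little as possible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import Grid, GridSpec, read_raster, write_raster

__all__ = [
    "NDVICube",
    "SeasonWindow",
    "AnnualSumStack",
    "DEFAULT_FLAG_WEIGHTS",
    "screen_quality",
    "fill_gaps_linear",
    "fill_cube_gaps",
    "savgol_adaptive",
    "savgol_adaptive_cube",
    "seasonal_sum",
    "write_cube",
    "read_cube",
    "write_sum_stack",
    "read_sum_stack",
]

DEFAULT_FLAG_WEIGHTS: dict[int, float] = {0: 1.0, 1: 0.5, 2: 0.0, 3: 0.0}

#: weight assigned to gap-filled observations when they re-enter the smoother
MIN_POSITIVE_WEIGHT = 0.1


@dataclass
class NDVICube:
    """Dated stack of vegetation-index grids with per-observation quality weights.

    ``values``/``quality``/``weights`` share shape (time, rows, cols); weight 0
    is synonymous with "observation missing" and such values are NaN.
    """

    spec: GridSpec
    dates: np.ndarray  # datetime64[D], strictly increasing
    values: np.ndarray
    quality: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        self.quality = np.asarray(self.quality)
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (self.values.shape == self.quality.shape == self.weights.shape):
            raise ValueError("values, quality and weights must share one shape")
        if self.values.shape[0] != len(self.dates):
            raise ValueError("one date per time layer required")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise ValueError("dates must be strictly increasing")
        if self.values.shape[1:] != self.spec.shape:
            raise ValueError("cube layers must match spec shape")

    @property
    def n_times(self) -> int:
        return len(self.dates)

    def copy(self) -> "NDVICube":
        return NDVICube(self.spec, self.dates.copy(), self.values.copy(),
                        self.quality.copy(), self.weights.copy())


@dataclass(frozen=True)
class SeasonWindow:
    """Growing-season window as inclusive (month, day) bounds within one year."""

    start: tuple[int, int] = (4, 1)
    end: tuple[int, int] = (10, 31)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("season start must precede season end")

    def contains(self, dates: np.ndarray) -> np.ndarray:
        idx = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[D]"))
        md = list(zip(idx.month, idx.day))
        return np.array([self.start <= t <= self.end for t in md])


@dataclass
class AnnualSumStack:
    """One ΣNDVI layer per year: values shape (n_years, rows, cols)."""

    spec: GridSpec
    years: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.years),) + self.spec.shape:
            raise ValueError("values must be (n_years, n_rows, n_cols)")

    def year_grid(self, year: int) -> Grid:
        k = int(np.flatnonzero(self.years == year)[0])
        return Grid(self.spec, self.values[k], self.mask.copy())

    def drop_year(self, year: int) -> "AnnualSumStack":
        keep = self.years != year
        return AnnualSumStack(self.spec, self.years[keep], self.values[keep], self.mask.copy())


def screen_quality(cube: NDVICube, flag_weight_map: dict[int, float] | None = None) -> NDVICube:
    """Assign fit weights from quality flags; weight-0 observations become missing.

    Raises KeyError naming any flag absent from the mapping.
    """
    fmap = DEFAULT_FLAG_WEIGHTS if flag_weight_map is None else flag_weight_map
    flags = np.unique(cube.quality)
    unknown = [int(f) for f in flags if int(f) not in fmap]
    if unknown:
        raise KeyError(f"quality flags without a weight mapping: {unknown}")
    out = cube.copy()
    lut = np.zeros(int(max(fmap) + 1))
    for k, w in fmap.items():
        lut[int(k)] = w
    out.weights = lut[cube.quality.astype(int)]
    out.values = np.where(out.weights > 0, cube.values, np.nan)
    return out


def fill_gaps_linear(
    times: np.ndarray,
    values: np.ndarray,
    min_weight: float = MIN_POSITIVE_WEIGHT,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill one pixel's missing observations by linear interpolation in time.

    Interior gaps are interpolated between the flanking valid observations;
    leading/trailing gaps take the nearest valid value.  Filled entries get
    weight *min_weight*.  Raises ValueError with fewer than two valid points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float).copy()
    valid = np.isfinite(y) & (w > 0)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid observations to fill gaps")
    filled = y.copy()
    gaps = ~valid
    # np.interp holds the edge values constant outside the valid range
    filled[gaps] = np.interp(t[gaps], t[valid], y[valid])
    w[gaps] = min_weight
    return filled, w


def fill_cube_gaps(cube: NDVICube, min_weight: float = MIN_POSITIVE_WEIGHT
                   ) -> tuple[NDVICube, np.ndarray]:
    """Gap-fill every pixel series; returns (cube, unusable mask).

    Pixels with fewer than two valid observations cannot be filled and are
    flagged unusable (masked in every downstream grid).
    """
    t = _time_axis(cube.dates)
    T = cube.n_times
    vals = cube.values.reshape(T, -1)
    wts = cube.weights.reshape(T, -1).copy()
    valid = np.isfinite(vals) & (wts > 0)
    n_valid = valid.sum(axis=0)
    unusable = n_valid < 2
    out_vals = vals.copy()
    need = np.flatnonzero((n_valid >= 2) & (~valid).any(axis=0))
    for p in need:
        v = valid[:, p]
        out_vals[~v, p] = np.interp(t[~v], t[v], vals[v, p])
        wts[~v, p] = min_weight
    out = cube.copy()
    out.values = out_vals.reshape(cube.values.shape)
    out.weights = wts.reshape(cube.values.shape)
    out.values[:, unusable.reshape(cube.spec.shape)] = np.nan
    return out, unusable.reshape(cube.spec.shape)


def _time_axis(dates: np.ndarray) -> np.ndarray:
    d = np.asarray(dates, dtype="datetime64[D]")
    return (d - d[0]).astype(float)


def _batched_wls_fit(values: np.ndarray, weights: np.ndarray, half_window: int,
                     poly_order: int) -> np.ndarray:
    """One pass of windowed weighted polynomial fitting.

    values/weights: shape (T, P).  Returns fitted values, shape (T, P); each
    point is the window fit evaluated at its own position (windows truncated
    at the series ends).  Windows whose weights are all zero fall back to an
    unweighted fit for that window.
    """
    T, P = values.shape
    fitted = np.empty_like(values)
    degenerate = False
    for tix in range(T):
        lo = max(0, tix - half_window)
        hi = min(T, tix + half_window + 1)
        x = np.arange(lo, hi, dtype=float) - tix
        A = np.vander(x, poly_order + 1, increasing=True)  # column 0 = value at tix
        Y = values[lo:hi]
        W = weights[lo:hi].copy()
        # all-zero or rank-deficient (fewer weighted points than coefficients)
        dead = (W > 0).sum(axis=0) <= poly_order
        if dead.any():
            degenerate = True
            W[:, dead] = 1.0
        M = np.einsum("wi,wp,wj->pij", A, W, A)
        r = np.einsum("wi,wp,wp->pi", A, W, Y)
        # tiny Tikhonov guard against exactly singular windows
        M += 1e-12 * np.eye(poly_order + 1)
        beta = np.linalg.solve(M, r[..., None])[..., 0]
        fitted[tix] = beta[:, 0]
    if degenerate:
        warnings.warn("window with all-zero weights: fell back to unweighted fit",
                      RuntimeWarning, stacklevel=3)
    return fitted


def savgol_adaptive(
    series: np.ndarray,
    weights: np.ndarray | None = None,
    half_window: int = 4,
    poly_order: int = 2,
    envelope_iters: int = 2,
    weight_decay: float = 0.5,
) -> np.ndarray:
    """Adaptive weighted Savitzky–Golay smoothing of one complete series.

    Each point is replaced by the value, at its own position, of a weighted
    least-squares polynomial of degree *poly_order* fitted over a window of
    ``2*half_window + 1`` points (truncated at the ends).  Then
    *envelope_iters* upper-envelope iterations follow: points lying below the
    current fit have their weights multiplied by *weight_decay* and the fit
    is repeated, pulling the curve toward the upper envelope of the data.
    """
    y = np.asarray(series, dtype=float)
    out = savgol_adaptive_cube(
        y[:, None], None if weights is None else np.asarray(weights, float)[:, None],
        half_window=half_window, poly_order=poly_order,
        envelope_iters=envelope_iters, weight_decay=weight_decay)
    return out[:, 0]


def savgol_adaptive_cube(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    half_window: int = 4,
    poly_order: int = 2,
    envelope_iters: int = 2,
    weight_decay: float = 0.5,
) -> np.ndarray:
    """Vectorised adaptive Savitzky–Golay over (T, ...) stacks of complete series."""
    if 2 * half_window + 1 <= poly_order:
        raise ValueError("window 2*half_window+1 must exceed poly_order")
    vals = np.asarray(values, dtype=float)
    T = vals.shape[0]
    if T <= 2 * half_window:
        raise ValueError("series length must exceed 2*half_window")
    shape = vals.shape
    flat = vals.reshape(T, -1)
    w = np.ones_like(flat) if weights is None else np.asarray(weights, float).reshape(T, -1).copy()
    fitted = _batched_wls_fit(flat, w, half_window, poly_order)
    for _ in range(int(envelope_iters)):
        below = flat < fitted
        w = np.where(below, w * weight_decay, w)
        fitted = _batched_wls_fit(flat, w, half_window, poly_order)
    return fitted.reshape(shape)


def seasonal_sum(cube: NDVICube, window: SeasonWindow, years,
                 unusable: np.ndarray | None = None) -> AnnualSumStack:
    """Sum (smoothed) composite values per pixel over the season window, per year.

    A composite belongs to the season iff its *start date* lies inside the
    window.  Raises ValueError listing any requested year with no in-window
    composites.
    """
    years = np.asarray(list(years), dtype=int)
    idx = pd.DatetimeIndex(cube.dates)
    in_window = window.contains(cube.dates)
    layers = []
    empty = []
    for y in years:
        sel = in_window & (idx.year == y)
        if not sel.any():
            empty.append(int(y))
            continue
        layers.append(cube.values[sel].sum(axis=0))
    if empty:
        raise ValueError(f"years with no in-season composites: {empty}")
    values = np.stack(layers)
    mask = ~np.isfinite(values).all(axis=0)
    if unusable is not None:
        mask |= unusable
    return AnnualSumStack(cube.spec, years, values, mask)


# ---------------------------------------------------------------------------
# Disk layout: directory of per-date GeoTIFF pairs + a CSV date table.


def write_cube(cube: NDVICube, directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    rows = []
    for k, date in enumerate(cube.dates):
        ds = np.datetime_as_string(date, unit="D")
        ipath, qpath = f"ndvi_{ds}.tif", f"quality_{ds}.tif"
        vals = cube.values[k]
        write_raster(Grid(cube.spec, np.where(np.isfinite(vals), vals, 0.0),
                          ~np.isfinite(vals)), os.path.join(directory, ipath))
        write_raster(Grid(cube.spec, cube.quality[k].astype(float)),
                     os.path.join(directory, qpath))
        rows.append({"date": ds, "index_path": ipath, "quality_path": qpath})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "dates.csv"), index=False)


def read_cube(directory: str | os.PathLike) -> NDVICube:
    table = pd.read_csv(os.path.join(directory, "dates.csv"))
    dates, values, quality = [], [], []
    spec = None
    for _, row in table.iterrows():
        g = read_raster(os.path.join(directory, row["index_path"]))
        q = read_raster(os.path.join(directory, row["quality_path"]))
        spec = g.spec
        vals = g.values.copy()
        vals[g.nodata_mask] = np.nan
        values.append(vals)
        quality.append(q.values.astype(int))
        dates.append(np.datetime64(row["date"]))
    cube = NDVICube(spec, np.array(dates, dtype="datetime64[D]"),
                    np.stack(values), np.stack(quality))
    cube.weights = np.where(np.isfinite(cube.values), 1.0, 0.0)
    return cube


def write_sum_stack(stack: AnnualSumStack, directory: str | os.PathLike) -> None:
    os.makedirs(directory, exist_ok=True)
    rows = []
    for k, year in enumerate(stack.years):
        path = f"sum_ndvi_{int(year)}.tif"
        write_raster(Grid(stack.spec, stack.values[k], stack.mask),
                     os.path.join(directory, path))
        rows.append({"year": int(year), "path": path})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "years.csv"), index=False)


def read_sum_stack(directory: str | os.PathLike) -> AnnualSumStack:
    table = pd.read_csv(os.path.join(directory, "years.csv"))
    grids = [read_raster(os.path.join(directory, p)) for p in table["path"]]
    mask = np.zeros(grids[0].spec.shape, dtype=bool)
    for g in grids:
        mask |= g.nodata_mask
    return AnnualSumStack(grids[0].spec, table["year"].to_numpy(),
                          np.stack([g.values for g in grids]), mask)
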