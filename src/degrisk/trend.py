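"""Per-pixel linear trend of annual growing-season ΣNDVI and its mapping.

For every pixel the annual ΣNDVI series is regressed on the year index
t = 0 … k−1 by ordinary least squares, so the intercept is the vegetation
level estimated at the first year and the slope is the ΣNDVI change per
year.  Slope significance comes from the usual t statistic with k−2
degrees of freedom.  Pixels are then grouped into four classes:

===== ==========================================  =========================
code  class                                       rule (defaults)
===== ==========================================  =========================
1     high negative vegetation trend              slope < 0, two-sided p ≤ 0.05
2     medium negative vegetation trend            slope < 0, 0.05 < p ≤ 0.10
3     low negative vegetation trend               slope < 0, p > 0.10
4     other                                       slope ≥ 0
===== ==========================================  =========================

i.e. class boundaries at the 95 % and 90 % confidence levels (one tail of
the negative slope).  The high+medium union is interpreted as degraded
land and serves as the binary outcome of the stage-2 risk model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import Grid, ZoneGrid, validate_stack
from .preprocess import AnnualSumStack

__all__ = [
    "TrendClassThresholds",
    "TrendResult",
    "fit_pixel_trend",
    "classify_trend",
    "binarize_degraded",
    "endpoint_sensitivity",
    "zonal_area_stats",
    "combined_total",
    "CLASS_HIGH",
    "CLASS_MEDIUM",
    "CLASS_LOW",
    "CLASS_OTHER",
]

CLASS_HIGH, CLASS_MEDIUM, CLASS_LOW, CLASS_OTHER = 1, 2, 3, 4

_CLASS_NAMES = {CLASS_HIGH: "high", CLASS_MEDIUM: "medium",
                CLASS_LOW: "low", CLASS_OTHER: "other"}


@dataclass(frozen=True)
class TrendClassThresholds:
    """Two-sided p ceilings for the high (95 %) and medium (90 %) classes."""

    p_high: float = 0.05
    p_medium: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.p_high < self.p_medium < 1.0):
            raise ValueError("require 0 < p_high < p_medium < 1")


@dataclass
class TrendResult:
    """Per-pixel OLS trend grids plus (optionally) the 4-class map."""

    slope: Grid
    intercept: Grid
    t_stat: Grid
    p_two_sided: Grid
    class_map: Grid | None = None


def fit_pixel_trend(stack: AnnualSumStack) -> TrendResult:
    """OLS of ΣNDVI on year index per pixel; t test on the slope (df = k−2).

    Degenerate pixels: a perfectly linear, non-constant series gets p = 0 and
    t = ±inf; an exactly constant series gets slope 0, p = 1.  Pixels masked
    in the stack stay masked.
    """
    k = len(stack.years)
    if k < 3:
        raise ValueError("need at least 3 years to fit a trend")
    t = np.arange(k, dtype=float)
    vals = stack.values.reshape(k, -1)
    mask = stack.mask | ~np.isfinite(stack.values).all(axis=0)

    tbar = t.mean()
    sxx = ((t - tbar) ** 2).sum()
    ybar = vals.mean(axis=0)
    sxy = ((t - tbar)[:, None] * (vals - ybar)).sum(axis=0)
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = vals - (intercept + slope * t[:, None])
    sse = (resid ** 2).sum(axis=0)
    dof = k - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        t_stat = slope / se
    p = 2.0 * stats.t.sf(np.abs(t_stat), dof)

    perfect = (sse <= 1e-24 * np.maximum(1.0, (vals ** 2).sum(axis=0)))
    sloped = np.abs(slope) > 0
    with np.errstate(invalid="ignore"):
        t_stat = np.where(perfect & sloped, np.sign(slope) * np.inf, t_stat)
    p = np.where(perfect & sloped, 0.0, p)
    constant = perfect & ~sloped
    t_stat = np.where(constant, 0.0, t_stat)
    p = np.where(constant, 1.0, p)

    shp = stack.spec.shape

    def grid(a: np.ndarray) -> Grid:
        return Grid(stack.spec, a.reshape(shp), mask.copy())

    return TrendResult(slope=grid(slope), intercept=grid(intercept),
                       t_stat=grid(t_stat), p_two_sided=grid(p))


def classify_trend(result: TrendResult,
                   thresholds: TrendClassThresholds = TrendClassThresholds()) -> Grid:
    """Assign the 4-class trend code from slope sign and two-sided p."""
    slope = result.slope.values
    p = result.p_two_sided.values
    cls = np.full(slope.shape, CLASS_OTHER, dtype=float)
    neg = slope < 0
    cls[neg] = CLASS_LOW
    cls[neg & (p <= thresholds.p_medium)] = CLASS_MEDIUM
    cls[neg & (p <= thresholds.p_high)] = CLASS_HIGH
    out = Grid(result.slope.spec, cls, result.slope.nodata_mask.copy())
    result.class_map = out
    return out


def binarize_degraded(class_map: Grid) -> Grid:
    """Merge high+medium negative trend into the binary 'degraded land' outcome."""
    cls = class_map.values
    valid = ~class_map.nodata_mask
    known = np.isin(cls[valid], (CLASS_HIGH, CLASS_MEDIUM, CLASS_LOW, CLASS_OTHER))
    if not known.all():
        raise ValueError("class map contains codes outside {1,2,3,4}")
    y = np.isin(cls, (CLASS_HIGH, CLASS_MEDIUM)).astype(float)
    return Grid(class_map.spec, y, class_map.nodata_mask.copy())


def endpoint_sensitivity(stack: AnnualSumStack,
                         thresholds: TrendClassThresholds = TrendClassThresholds()
                         ) -> dict[str, float]:
    """Agreement of the class map with maps omitting the first / last year.

    Returns percent of unmasked cells identically classified for each reduced
    stack, diagnosing the leverage of the series endpoints.
    """
    if len(stack.years) < 4:
        raise ValueError("need at least 4 years for an endpoint check")
    full = classify_trend(fit_pixel_trend(stack), thresholds)
    out = {}
    for label, year in (("drop_first", stack.years[0]), ("drop_last", stack.years[-1])):
        reduced = classify_trend(fit_pixel_trend(stack.drop_year(int(year))), thresholds)
        valid = ~(full.nodata_mask | reduced.nodata_mask)
        agree = (full.values[valid] == reduced.values[valid]).mean() * 100.0
        out[label] = float(agree)
    return out


def zonal_area_stats(class_map: Grid, zones: ZoneGrid) -> pd.DataFrame:
    """Areal statistics per zone and trend class, with a medium+high column.

    One row per zone plus a TOTAL row.  Areas in hectares
    (cell count × cell_size² / 10⁴); percentages relative to the zone's
    unmasked cell count (sum to 100 per zone).  Columns mirror the low /
    medium / high / medium+high convention of district degradation tables.
    """
    validate_stack([class_map, zones]).raise_if_failed()
    ha_per_cell = class_map.spec.cell_area / 1e4
    valid = ~(class_map.nodata_mask | zones.nodata_mask)
    rows = []
    zone_ids = zones.zone_ids()
    for zid in zone_ids:
        inz = valid & (zones.values == zid)
        n = int(inz.sum())
        row: dict[str, object] = {"zone": int(zid)}
        counts = {}
        for code, name in _CLASS_NAMES.items():
            c = int((class_map.values[inz] == code).sum())
            counts[name] = c
            row[f"{name}_ha"] = c * ha_per_cell
            row[f"{name}_pct"] = 100.0 * c / n if n else 0.0
        row["medhigh_ha"] = (counts["medium"] + counts["high"]) * ha_per_cell
        row["medhigh_pct"] = (100.0 * (counts["medium"] + counts["high"]) / n) if n else 0.0
        row["n_cells"] = n
        rows.append(row)
    df = pd.DataFrame(rows)
    total: dict[str, object] = {"zone": "TOTAL"}
    n_all = int(df["n_cells"].sum())
    for name in list(_CLASS_NAMES.values()) + ["medhigh"]:
        total[f"{name}_ha"] = float(df[f"{name}_ha"].sum())
        total[f"{name}_pct"] = (100.0 * df[f"{name}_ha"].sum() / (n_all * ha_per_cell)
                                if n_all else 0.0)
    total["n_cells"] = n_all
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def combined_total(medium_ha, high_ha) -> float:
    """TOTAL of the medium+high ('degraded land') column from per-zone areas.

    This is the aggregation convention of the areal-statistics table: the
    combined column is the cellwise medium+high sum per zone and the TOTAL
    row sums the zones.
    """
    medium_ha = np.asarray(medium_ha, dtype=float)
    high_ha = np.asarray(high_ha, dtype=float)
    if medium_ha.shape != high_ha.shape:
        raise ValueError("medium and high area vectors must align")
    return float((medium_ha + high_ha).sum())
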