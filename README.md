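# degrisk

Two-stage analysis of cropland degradation in irrigated drylands:

1. **Trend mapping.** Per-pixel linear trends of growing-season-summed NDVI
   (ΣNDVI) are estimated from 16-day satellite composites after quality
   screening, gap filling and adaptive Savitzky–Golay smoothing. Pixels with a
   significantly negative slope are classified as degrading (high: two-sided
   p ≤ 0.05, medium: p ≤ 0.10, both with slope < 0), and the high+medium union
   becomes a binary *degraded land* map.
2. **Risk modelling.** The degraded-land outcome is regressed on aligned
   environmental and management factor rasters (groundwater table depth and
   salinity kriged from wells, land-use change and abandonment flags, soil
   fertility classes, canal/drain densities and distances, slope, district
   water-use variability) with a spatial logistic model

   P(y = 1 | x) = 1 / (1 + exp(−(β₀ + Σᵢ βᵢ xᵢ))),

   preceded by one-cell-per-3×3-window sampling (to thin spatial
   autocorrelation), a 50/50 calibration/validation split and a VIF > 5
   multicollinearity screen. A full fit and a backward-stepwise reduction are
   compared on validation AUC with a correlated-AUC (DeLong) test; the kept
   model is validated by ROC/AUC, percent correctly predicted (PCP) at
   p = 0.5, and the likelihood-ratio χ². Coefficients are reported with their
   odds interpretation, 100·(e^β − 1) percent change in the odds of
   degradation per unit of the predictor. Finally the fitted probabilities
   are cut into ten equal-count classes (class 1 = top decile of risk).

The package ships a synthetic-scenario generator (`degrisk.synthetic`) that
builds a complete artificial study region — NDVI cube with planted linear
declines, spatially autocorrelated factor fields, wells, land-use series,
districts — with known ground truth, so the whole pipeline is testable end to
end without external data. It is aimed at remote-sensing and land-management
analysts who want a reproducible, fully parameterised reference
implementation of this analysis pattern.

## Worked example

Run the full pipeline on the default synthetic region (120×120 cells of
250 m, 11 years × 23 composites, logistic truth β₀ = −3.55 with five nonzero
effects):

```bash
degrisk all --scenario scn --out out --seed 42 --overwrite -v
```

or from Python:

```python
from degrisk import PipelineConfig, run_pipeline
cfg = PipelineConfig(scenario_dir="scn", out_dir="out", seed=42)
run_pipeline(cfg, overwrite=True)
```

Selected output for seed 42 (`out/model_full.csv`, `out/validation.json`,
`out/endpoint_sensitivity.json`):

```
    variable  coefficient  odds_percent    se      z     p stars
uncultivated        0.884       142.020 0.240  3.676 0.000  ****
   slope_pct        0.450        56.778 0.197  2.286 0.022    **
    gw_table        1.449       325.815 0.311  4.653 0.000  ****
 gw_salinity        0.075         7.756 0.133  0.562 0.574  n.s.

validation: AUC 0.653, PCP 61.6 %, chi-square 67.96 (df 7, p < 0.001)
endpoint sensitivity: 87.9 % / 88.1 % agreement without first / last year
```

Reading it: the groundwater-table coefficient 1.449 means each additional
metre of groundwater depth multiplies the odds of degradation by e^1.449,
i.e. raises them by ≈ 326 % — close to the generating value 1.46 used by the
scenario. The endpoint-sensitivity numbers say that dropping the first or
last year of the ΣNDVI series leaves ~88 % of pixels in the same trend
class, so the mapped trend is not an artefact of the series endpoints.
`out/` also contains the 4-class trend map, the per-district areal-statistics
CSV (hectares and percent per class, with the medium+high "degraded land"
column), the VIF table, the sample table, and the decile risk map plus the
probability surface as GeoTIFFs.

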