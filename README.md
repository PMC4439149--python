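# reefcpue

Spatiotemporal analysis of catch-per-unit-effort (CPUE) for GPS-logged dive
fisheries — built around the abalone case, where every harvested shell is
"swiped" through a GPS-enabled measuring board, leaving a stream of
geo-located, time-stamped shell lengths.

The package turns swipe streams, logbook effort hours and a bathymetric DEM
into:

1. **Filtered catch records** — vessel-transit outliers (implied speed above
   a threshold) and reef-mismatch positions (farther than the ~100 m
   umbilical from mapped reef) removed; shell length SL (mm) converted to
   whole weight via the allometric law W = 0.000412 (SL/10)^2.76 kg; logbook
   hours apportioned evenly over each diver-day's swipes.
2. **Gridded CPUE** — 1-ha (100 m) cells, per year:
   CPUE = Σcatch / Σeffort (kg/h). Unfished cells carry no value.
3. **Spatial autocorrelation** — global Moran's I
   `I = (n/S0) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²` over binary
   fixed-distance bands (125–1500 m), z-scores under the randomization
   null; and the local Getis-Ord Gi\* statistic (self-inclusive, z-form) at
   the 250 m band.
4. **Hotspot persistence** — annual binary hot layers (Gi\* z > 1.65)
   overlaid into a cumulative map whose class (1–4) counts the years a cell
   was a significant hotspot; plus reef-fraction-fished metrics, overall and
   within the 5–15 m diving depth band.
5. **Terrain covariates** — slope, complexity (slope of slope), bathymetric
   position index (50/150 m annulus), rugosity and vector ruggedness from
   the DEM, screened for collinearity at |r| > 0.7, averaged per cell.
6. **An additive model of log-CPUE** —
   `log CPUE ~ s(complexity) + s(depth) + s(BPI) + (1 | year)`,
   Gaussian, penalized regression splines with REML smoothing selection,
   year as a random intercept, per-term edf/F/p, AIC (with
   smoothing-uncertainty correction) and partial-effect curves with 95%
   intervals.

Because commercial dive data are proprietary, the package ships a
first-class synthetic generator (`reefcpue.synth`): a reef/sediment DEM
with planted rugose reefs, and multi-year diver swipe streams with planted
hotspot centres, planted transit outliers and exact ground truth — so every
stage of the pipeline is validated against known structure.

## Worked example

```python
from reefcpue.config import PipelineConfig
from reefcpue.pipeline import run_pipeline

result = run_pipeline(PipelineConfig(seed=0), "out/")
print("sensitivity, specificity:", result["recovery"])
print(result["fit"].summary())
```

prints (seed 0):

```
sensitivity, specificity: (1.0, 0.98)
log-CPUE additive model | smooths: complexity_mean, depth_mean, bpi_mean | random: year | rows dropped in join: 4
Gaussian additive model (penalized splines, REML)
n = 210    edf(total) = 10.81    scale = 0.1624    AIC = 230.40

term                             edf         F           p
complexity_mean                 3.42     10.90      <0.001
depth_mean                      1.00      1.16       0.283
bpi_mean                        3.79     47.83      <0.001
year (random intercept)         1.60                        sd = 0.061
```

All three planted hotspots are recovered (every planted cell is a
significant hotspot in at least one year; 98% of fished-but-unplanted cells
are not). The model finds strongly significant complexity and BPI effects
on log-CPUE — the planted hotspots sit on rugose reef crests — while depth,
which was not planted as a driver in this scenario, stays near-linear and
insignificant. The per-year Moran profile in `result["profile"]` shows
z-scores of 6–10 at the 125 m and 250 m bands falling to ≈0 at 1500 m —
CPUE clusters at the scale of individual reefs, not the whole ground.

The same stages are available from the shell:

```bash
reefcpue run --seed 0 --out out/          # everything at once
reefcpue simulate --seed 0 --out data/    # or stage by stage
reefcpue ingest --swipes data/swipes.csv --logbook data/logbook.csv \
    --reef-mask data/reef_mask.asc --out out/
reefcpue report --outdir out/
```

Artefacts are plain text throughout: CSV tables, GeoJSON vectors, ESRI
ASCII-grid rasters, JSON reports, plus a run manifest with the
configuration hash and per-stage counts.

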