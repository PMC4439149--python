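# Methods

## The analysis, end to end

The pipeline estimates where and how persistently a dive fishery
concentrates its catch rate, and how that pattern relates to seafloor
structure. Its stages, in order: ingest and filter swipe records; grid
catch and effort into 1-ha cells; compute terrain derivatives from the DEM;
profile spatial autocorrelation of CPUE over distance bands; detect annual
hotspots and their multi-year persistence; quantify the fished fraction of
the reef; and fit an additive model of log-CPUE on terrain covariates.
Everything operates in a projected metric plane — distance-band statistics
are meaningless in degrees, so geographic inputs must be projected before
ingestion.

## Ingest and filtering

A swipe record is one measured shell: diver, instant, position, maximum
shell length. Two artefact filters run before any spatial step.

**Transit filter.** Within each diver-day, ordered by time, a record whose
straight-line speed from the previous *retained* record exceeds a threshold
is removed. Comparing against the last retained record (streaming removal)
prevents one transit leg from cascading into the removal of the next
legitimate swipe. The threshold defaults to 2.0 m/s (≈4 knots): clearly
above diver-drift speeds (a tethered diver works within ~100 m of the
vessel), clearly below vessel transit speed. The source workflow does not
print its cut-off, so the value is configurable.

**Reef-mismatch filter.** Records farther than `buffer_m` (default 100 m,
the umbilical length) from the nearest reef pixel centre are removed. An
empty reef mask removes everything, with a warning — by design, since it
signals a co-registration mistake.

The filters commute whenever they flag disjoint record sets; the order used
is transit first, then mismatch (also configurable by running the
operations individually). Retained records get a weight from the
allometric law W = 0.000412 (SL/10)^2.76 (kg, SL in mm) and an even share
of the diver-day's logbook hours, so per-day apportioned hours sum exactly
to the logbook.

## Gridding

Cells are 100 m squares (1 ha), half-open on both axes (a point on an
interior boundary belongs to the higher-index cell), with the grid origin
snapped to the DEM origin so terrain zonal means align exactly. Per cell
and year, CPUE is the ratio of sums Σcatch/Σeffort — not the mean of
per-record ratios — matching the catch-divided-by-hours definition and
robust to unequal apportionment. Cells with zero effort are absent, not
zero: the analysis concerns fished cells, and treating unfished reef as
CPUE = 0 would manufacture coldspots.

## Terrain derivatives

Depth is stored positive-down; operators that care about sign use
elevation = −depth, so crests get positive BPI.

- **Slope** — Horn 3×3 finite differences, degrees.
- **Complexity** — the slope operator applied to the slope raster ("rate of
  change of slope"). Any plane has zero complexity. The exact operator
  behind the verbal definition is an interpretation; slope-of-slope is the
  implementation here.
- **BPI** — focal elevation minus the mean elevation over the annulus of
  pixels whose centre distance d satisfies inner < d ≤ outer (defaults
  50/150 m). Zero on planes of any tilt (centrosymmetric annulus).
- **Rugosity** — triangulated 3-D surface area over planar area in a 3×3
  window (two triangles per unit cell); exactly 1 on flat seafloor.
- **VRM** — 1 − |resultant of unit surface normals|/n over a 3×3 window;
  0 for flat *and* uniformly tilted terrain, approaching 1 for disordered
  terrain. Window sizes for rugosity/VRM are unstated upstream; the common
  3×3 default is used and exposed.

Edge policy: a pixel whose full window or annulus leaves the raster, or
contains nodata, is nodata. Per-cell covariate means average the valid
pixels in each 1-ha cell. The collinearity screen computes pairwise Pearson
correlations of the per-cell means and greedily drops variables with
|r| > 0.7, visiting variables in a priority order that protects complexity
and BPI (the structural variables conventionally retained).

## Spatial statistics

Neighbourhoods are binary fixed-distance bands on cell centroids:
w_ij = 1 iff 0 < d(i,j) ≤ band. Only fished cells enter.

**Global Moran's I** with E[I] = −1/(n−1) and, by default, the
randomization (permutation) variance for the z-score — the common GIS
default; the normality variance is an option. Isolated cells (no neighbour
within the band) are dropped and counted, not silently zero-weighted.
Degenerate bands — a near-complete neighbour graph makes the null variance
non-positive — are reported per band by the profile rather than failing the
run. The profile spans 125, 250, 500, 750, 1000 and 1500 m.

**Local Gi\***, the self-inclusive Getis-Ord statistic in z-form, at the
250 m band. The workflow this reproduces names "Gi" but used standard GIS
hot-spot tooling, which computes Gi\*; plain Gi (self-exclusive) is
available behind a flag. No multiple-testing correction is applied to the
z > 1.65 cut, matching the conventional workflow; binarization is strict
(z = 1.65 exactly is not hot).

**Cumulative persistence.** Annual hot layers are overlaid as a per-cell
count of significant years (classes 1–Y, non-consecutive years count), the
reading of a "union overlay into classes by number of years fished".
Coldspots are computed and reported but excluded from the cumulative map.

## Additive model

log CPUE (natural log; safe because unfished cells are excluded) is
modelled as a Gaussian additive model: penalized cubic B-spline smooths
(second-order difference penalty, sum-to-zero constraint, basis dimension
10 per term) for complexity, depth and BPI, plus a year random intercept
implemented as ridge-penalized dummies — the exact mixed-model equivalence
λ = σ²/σ_b². Smoothing parameters are selected by REML (GCV is available
but undersmooths in null simulations); each smooth's penalty null space
after the constraint is the linear function, so edf shrinks to 1 when the
data carry no curvature. Per-term F and p are the approximate Wald-type
quantities conventional for penalized smooths. AIC uses the
smoothing-parameter-uncertainty corrected degrees of freedom
τ = tr(F) + tr(X'X·J·V_ρ·J')/σ̂² (J = ∂β̂/∂ρ analytic, V_ρ from a
finite-difference REML Hessian); in nested-model simulations this
correction brings AIC selection in line with the reference behaviour of
established additive-model software (23/25 vs 22/25 correct selections on
shared data). A `select=True` mode adds null-space shrinkage penalties so
terms can be removed entirely; it is not used for AIC comparison because it
collapses AIC differences between nested models. Model choice across
candidate term sets is lowest AIC, ties to fewer terms. Partial effects
are centred over the observed covariate values, carry 95% pointwise
intervals from the Bayesian posterior covariance, and refuse extrapolation.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so recovery is exactly scorable.

*Seafloor*: a smooth sediment surface (Gaussian-filtered white noise,
correlation length 300 m, SD 4 m, clipped to 3–25 m depth) with three
non-overlapping rugose reef bumps (radius 450 m, 8 m relief, extra
fine-scale roughness on top), placed by best-candidate sampling so reefs
spread widely over the 4.5 × 3 km extent. The reef mask is the union of
bump footprints, so it has exactly `n_reefs` connected components.

*Fishery*: six divers, four years (2008–2011 style), 12 dive-days per
diver-year at ~5 h each — ≈1400 h total, the scale of a small commercial
zone. Each dive anchors either at a planted hotspot centre (probability ∝
intensity; intensity multiplies the swipe rate, not the hours, so planted
centres carry genuinely higher CPUE — here 3× background) or at one of
nine habitual background "grounds" on reef, emulating fleets that revisit
known grounds rather than covering reef uniformly; with these defaults
roughly half the reef cells are ever fished. Within a dive the diver
random-walks (5 m steps, ≥20 s gaps) inside the 100 m drift disc; shell
lengths are normal (140 ± 12 mm) truncated at the 120 mm legal minimum.
A configurable fraction of inter-swipe gaps (2%) becomes a transit
excursion whose implied speed is at least the vessel transit speed
(3 m/s); these indices are the planted outliers. Ground truth records, per
year, the 1-ha cells whose rectangle intersects an active centre's drift
disc — exactly the cells that can receive hotspot swipes.

Not emulated: diver behavioural realism (search, giving-up densities),
population dynamics or depletion, tides and positioning error, disease
dynamics, and any dependence of swipe rate on handling time. Passing
recovery tests therefore shows the *pipeline* recovers planted structure
under realistic geometry and noise — not that real fisheries data are this
clean.

## Numerical choices and problem sizes

Filters and aggregations are exact (conservation asserted to 1e-9); the
spatial statistics are closed-form and checked against brute-force
transcriptions to 1e-10 and against an independent R implementation of
Moran's I to 1e-8 (row-standardized form). Terrain closed forms (plane →
zero slope/complexity/BPI/VRM, rugosity 1) hold to 1e-9. The additive-model
REML optimum is found by Nelder-Mead on log-smoothing-parameters from two
starts; a 1e-10 diagonal ridge guards the intercept/dummy collinearity.
The test suite uses a 2 × 1.5 km two-reef scenario for speed; the default
scenario (4.5 × 3 km, ~40,000 swipes, ~240 cell-years) runs end to end in
about ten seconds, and the full suite — including a 10,000-permutation
Moran calibration check and 60 model fits for recovery/null simulations —
in well under two minutes on one CPU.

## Known limitations

- The reef-mismatch distance is measured to reef pixel centres, so the
  effective buffer is accurate to half a pixel.
- Gi* inference ignores multiple testing by design (mirroring the
  conventional workflow); an FDR variant is a natural extension.
- The year effect is a random intercept only; random smooths by year and
  spatial residual correlation are out of scope.
- ASCII-grid rasters carry no CRS metadata; the pipeline assumes all
  inputs share one projected CRS in metres.
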