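# Methods

`palmarea` re-implements, as a tested pipeline on synthetic scenes, the
workflow used to map plantation crops from multi-sensor satellite imagery and
to convert the map into defensible area and emissions accounts: percentile
compositing of a cloudy optical time series, a 17-predictor feature stack, a
Random-Forest six-class map with majority filtering, an error-matrix accuracy
assessment, stratified bias-corrected area estimates with 95% confidence
intervals, zonal accounting against concession polygons, and carbon-emission
arithmetic. This note records the model assumptions, the defaults and why
they were chosen, and what the synthetic experiments do and do not
demonstrate.

## The classification and accounting procedure

**Compositing.** Each optical date is screened for clouds by the union of the
scene QA mask and spectral tests (bright in blue *and* SWIR; optionally a
cirrus-band test when a cirrus layer is present). Per pixel and band, the
composite is the mean of all clear observations falling inside the closed
[p_lo, p_hi] percentile interval of the per-pixel series (defaults 40–60,
linear interpolation between order statistics). This trimmed mean discards
residual bright (cloud) and dark (shadow) outliers that per-date screening
missed. If the interpolated interval captures no observation — possible for
short series — the single observation nearest the series median is used
rather than leaving a hole. Pixels with fewer than `min_obs = 3` clear
observations are nodata: a one- or two-scene "composite" is not a composite.

**Features.** The 17 predictors are the ten optical bands (B2–B8A, B11–B12),
NDVI = (B8 − B4)/(B8 + B4), the 5×5 moving-window population SD of NDVI
(texture), temporal mean and population SD of the VV and VH SAR channels, and
slope. NDVI and its texture are computed on the 10 m grid before aggregation.
Slope uses Horn's 3×3 gradient on the native 30 m DEM (the common DEM
convention) and is resampled bilinearly to the analysis grid; computing the
derivative on the native grid avoids resampling artefacts. All 10 m layers
are aggregated to the 20 m analysis grid by exact 2×2 block means; window
statistics shrink at image edges instead of inventing padded values. A pixel
nodata in any optical band is nodata in all 17 layers.

**Classification.** Reference polygons are rasterized by pixel-center
membership on the analysis grid. The sample is split 50/50 per class; the
split unit is configurable between individual pixels and whole polygons, and
the pipeline defaults to polygons: within-polygon pixels are spatially
autocorrelated, and letting them straddle the train/test boundary leaks
information and inflates test accuracy — a well-known pitfall of clustered
reference data. A Random Forest with 100 trees and 4 variables per split
(≈ √17) is fitted, the map predicted per pixel, and a 3×3 majority (mode)
filter applied; ties retain the center pixel's class, which is conservative
and deterministic. The filter never introduces a class absent from the
window.

**Accuracy and areas.** The error matrix counts test pixels by mapped class
(rows) and reference class (columns), with mapped pixel totals N_i taken from
the filtered map. Overall, user's and producer's accuracies are reported in
both the plain sample-count form and the map-share-weighted form. Class areas
use the standard stratified (mapped-class strata) estimator:

    W_i = N_i / ΣN_i,   p̂_·j = Σ_i W_i n_ij / n_i·,   Â_j = p̂_·j A_total,
    SE(p̂_·j) = sqrt( Σ_i W_i² q_ij(1−q_ij) / (n_i·−1) ),  q_ij = n_ij/n_i·,

with 95% intervals Â_j ± 1.96·SE·A_total. Σ_j Â_j = A_total identically. The
matrix is serialized with explicit "mapped"/"reference" axis labels so a
transposition cannot pass silently. A mapped stratum with ≤1 test sample is a
hard error (variance undefined), never silently dropped. A Monte-Carlo
routine validates the intervals: for a known landscape and confusion model it
repeatedly draws stratified test samples and measures how often the intervals
contain the truth.

**Zonal accounting and emissions.** A pixel belongs to a zone iff its center
lies inside the polygon — the same pixel-count basis as the estimator, and
exactly testable. Zones of different kinds (concession / district / park) may
overlap and each receives the pixel; same-kind overlaps are unioned before
kind-level totals. Within-concession estimates are produced either by
proportional allocation of the regional bias-corrected estimate (default) or
by re-running the estimator with concession-restricted strata; the default
avoids the small-stratum failures the restricted mode invites on modest
scenes. Emissions from clearing: CO2e [Tg] = area [ha] × carbon density
[Mg C/ha] × 44/12 × 10⁻⁶, density defaulting to 209.3 Mg C/ha (a regional
aboveground mean); belowground and soil pools are excluded. The exact molar
ratio 44/12 is the default conversion and is always reported alongside the
result, since rounding it changes the headline number at the 0.1 Tg level.
Acres convert at exactly 0.40468564224 ha/ac.

## The synthetic-data generator

The generator emulates the inputs of a dry-season plantation-mapping campaign
in a projected metric CRS (UTM 47N), with the mixed native resolutions of the
real sensors: 10 m optical/SAR, 30 m DEM, 20 m analysis grid.

**Landscape.** A Gaussian-smoothed random field is thresholded at the
empirical quantiles of the cumulative class weights, giving contiguous
patches whose class frequencies match the weights essentially exactly. The
field is generated at an 80 m management-block granularity (`stand_block = 8`
native pixels) and replicated, for two reasons: industrial plantations are
laid out in rectangular management units of roughly this size, and stand
edges then coincide with the 20 m analysis grid, so every analysis pixel has
an unambiguous true class. Default class weights (0.15, 0.15, 0.30, 0.20,
0.12, 0.08) mirror a landscape where other trees dominate and water is the
smallest class. The default scene is 256×256 native pixels (≈ 2.6 km side,
655 ha) with eight optical and SAR dates.

**Radiometry.** Each class carries a 10-band reflectance signature and a
(VV, VH) backscatter signature. Oil palm, rubber and other trees are close in
the visible bands and separated mainly in the red-edge region and weakly in
SAR; shrub sits between the tree classes and bare ground — the confusion
structure that motivates red-edge bands in real tree-crop mapping. Three
noise layers sit on the signatures:

* *per-date noise* (`optical_sd = 0.04` reflectance; lognormal speckle of
  2.0/2.4 dB in SAR, i.e. Gaussian in dB and multiplicative in linear power,
  modelling multi-looked scenes) — this is what compositing averages away;
* *static pixel effects* — date-independent, i.i.d. across pixels
  (fractional for optical, default 0.12 of the band mean; 1.0 dB for SAR):
  canopy-scale texture that survives temporal averaging;
* *stand effects* — date-independent fields drawn per ~200 m cell with
  Student-t (df = 3) tails and light smoothing (0.02 fractional optical,
  0.25 dB SAR): stand age, soil and moisture
  gradients that shift whole stands coherently, with occasional extreme
  stands (burned shrub, flooded bare ground). An additive reflectance floor
  (0.02) represents atmospheric-correction residuals and keeps dark classes
  (water) from being implausibly noise-free.

The static and stand amplitudes were calibrated so that the pipeline's test
accuracy lands in the low-to-mid 90s — the accuracy regime reported for real
Sentinel-based six-class maps of this kind — while post-filter map agreement
with truth stays above 0.9. Without irreducible within-class heterogeneity a
synthetic scene is trivially separable: test accuracy saturates at 1.0,
standard errors collapse to zero, and the interval machinery is untestable.

**Clouds.** Cloud contamination is planted as contiguous blobs (smoothed
noise thresholded at the exact coverage quantile), not i.i.d. pixels, so
percentile compositing is genuinely stressed; contaminated pixels are painted
with bright, spectrally flat reflectance, high in blue and SWIR, and flagged
in the QA mask. Default cover is 30% per date.

**Vectors.** Reference polygons are squares placed wholly inside single-class
regions (erosion by exactly the polygon footprint), on a separation lattice
so no two polygons of a class overlap. Placement effort is allocated to
classes proportionally to their area share (minimum four polygons): equal
allocation would over-represent small classes inside each map stratum and
bias the estimator's correction of the large classes. Polygons may extend to
stand edges — still single-class by construction — so the reference sample
sees the same filter-window conditions as the map at large. Zone polygons are
random rectangles (concessions, parks; concessions may overlap parks, as real
grants do) and an equal-width strip partition for districts. The DEM is a sum
of low-frequency surfaces on its own 30 m grid, with a flat option for
degenerate-slope tests.

**What the generator does not model.** Radiative transfer, viewing geometry
and BRDF; cloud shadows; orbit-direction artefacts; label staleness from
mixed reference vintages; georeferencing error; sub-pixel mixing at stand
edges (truth is block-aligned by design). Passing tests demonstrate that the
*method* is implemented correctly and that the interval estimator covers
under a landscape whose error process is representative of its reference
sample — not that any particular real-world map reaches these accuracies.

## Numerical and statistical choices

* Percentile definition: linear interpolation (the numpy default); the
  retention interval is closed on both ends.
* All SDs (temporal SAR, NDVI texture, the two-point example) are population
  SDs (divide by n).
* Cloud-rule constants (blue 0.25, SWIR 0.20, cirrus 0.01 when enabled) are
  configuration, not physics; the rule's *shape* — QA union spectral tests —
  is fixed.
* Stratified split uses the floor rule per class; seeded shuffles; model seed
  and split seed are independent keys derived from one master seed via
  `SeedSequence`, so every stage is independently reproducible.
* Truth comparison restricts to mapped (non-nodata) pixels: the estimator
  accounts for the area it maps, and cloud-gap pixels are outside its
  population.
* The end-to-end synthetic check (default configuration, ~660 ha scene,
  ~350 km² would be the real analogue) asks the 95% intervals to contain the
  true class areas for at least five of six classes and post-filter agreement
  with truth ≥ 0.9. Problem sizes (256×256 scene, 8 dates, 1000-rep coverage
  simulations at n_test = 500) keep the full suite runnable on one CPU in
  minutes while leaving Monte-Carlo tolerances meaningful.

## Known limitations

* Reference samples are polygon-clustered; the variance estimator assumes
  independent pixels within strata and therefore understates variance when
  errors are stand-correlated. The polygon-level split and area-proportional
  allocation reduce, but do not eliminate, this — the same caveat applies to
  real studies built on polygon reference data, and no cluster correction is
  applied here by design.
* The majority filter trades isolated-pixel noise for a minimum-mapping-unit
  bias against features smaller than the window; with 80 m stands the effect
  is small but not zero.
* "Majority of connected pixels" is read as the standard 3×3 mode filter; a
  connected-component sieve is a plausible alternative reading and is not
  implemented.
* The cirrus screening band is represented only through the optional
  threshold (the synthetic stack carries the ten classification bands);
  enabling the cirrus test on data without a B10 layer is an error by
  contract.
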