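# Methods

## The estimation problem

Canopy nitrogen content (CNC, percent of leaf dry mass) in rice changes with
developmental stage, variety and nitrogen supply. The package estimates it
from multispectral reflectance via the red-edge index
NDRE = (ρ800 − ρ720)/(ρ800 + ρ720) and uses the resulting six-stage
trajectories (tillering TS → jointing JS → panicle initiation PIS → booting
BS → full heading FHS → milk ripening MRS) to screen collections for a
high-NUE phenotype.

## Radiometric calibration

The sensor is modelled as linear per band: ρ_λ = DN_λ·Gain_λ + Offset_λ.
Gain and offset are estimated by ordinary (unweighted) least squares over the
six ground panels of known reflectance {0.03, 0.12, 0.24, 0.36, 0.56, 0.80};
panel DN is the arithmetic mean of the rectangle's interior pixels. Each band
is fitted independently; residual RMSE per band is reported. Output
reflectance is not clipped by default (so calibration faults stay visible); a
clip flag bounds it to [0, 1.2]. Degenerate inputs — fewer than two panels,
or identical panel DNs in a band — raise rather than silently producing a
flat line.

## Vegetation indices

Indices are computed from plot-mean reflectance ("index of means"), matching
the one-value-per-plot convention of field practice; mean-of-per-pixel
indices differs in general and is deliberately not used. Band lookup is by
exact nominal center; a raster without the 800 or 720 nm band is an error,
never a nearest-band substitution. Normalized-difference indices are bounded
in (−1, 1) for positive reflectance, and NDRE is strictly increasing in ρ800
and decreasing in ρ720 — both are enforced as property tests.

## Nitrogen models

* **Model I** (quadratic): N% = a·NDRE² + b·NDRE + c, least squares via the
  normal equations. Tillering-stage data are excluded before fitting: at TS
  the canopy has not closed and the water background (near-zero NIR
  reflectance) biases plot NDRE low relative to the canopy's nitrogen status.
* **Model II** (exponential): N%·LAI = α·e^(β·NDRE), fitted by nonlinear
  least squares on the original scale (error structure on y), initialized
  from the OLS fit of log y on NDRE; when some y ≤ 0 the initializer falls
  back to a configurable starting point. All six stages are used: the LAI
  factor absorbs the canopy-structure signal that distorts Model I at TS.
  LAI = LA_S × d with plant density d = 22.5 plants/m² by default.

Fit quality is summarized by pseudo-R² = 1 − SSres/SStot (identical to the
ordinary R² for the linear fits), adjusted R² = 1 − (1 − R²)(n − 1)/(n − k)
with k the number of estimated coefficients (3 and 2 respectively), the
Pearson correlation of observed vs fitted values, and a two-sided F-test
p-value. Both plain and adjusted R² are always reported. Correlations use the
product-moment formula with the exact t-transform for p-values; no
multiple-testing correction is applied. Varieties are split into early/late
maturation at 100 days growth duration; the boundary day is assigned to the
late group (the cutoff itself is standard, its inclusivity is a package
choice).

## Phenotype screen

The qualitative high-NUE signature — moderately high vegetative nitrogen,
the collection's highest nitrogen at FHS and MRS, and a slow post-booting
decline — is operationalized by three configurable clauses
(`PhenotypeRule`):

1. rank at FHS and at MRS ≤ `reproductive_rank_max` (default 1; rank 1 is
   the highest value, ties share the minimum rank);
2. each of TS, JS, PIS, BS inside the `vegetative_band` percentile interval
   of that stage's distribution (default [40, 95], which rejects
   early-peaking varieties that are vegetative-maximal);
3. BS→MRS decline rate (value(BS) − value(MRS))/2 at or below the
   collection's `decline_quantile_max` quantile (default 0.5, the median).

The endpoint-based decline rate is preferred over a fitted slope: with six
stages it is robust and directly expresses "gradually decreasing" after
booting. Negative rates (late nitrogen rise) are allowed and flagged.
Varieties with missing stages are excluded with a warning, never silently
passed; fewer than five complete varieties is an error because percentile
bands lose meaning. The classifier is monotone in rule laxity: relaxing any
threshold can only add flags (property-tested).

Field traits follow standard yield bookkeeping: SSR = 100·full/total grains,
GNP = full grains/EPN, TGW = 5 × (200-grain weight), GY[kg/ha] =
GYP[g] × plants/area[m²] × 10 (the ×10 folds the g→kg and m²→ha
conversions of the ×10,000 area scaling), NUE = GY per kg N applied —
undefined at the 0 kg/ha treatment and reported as missing there. An
optional multiplicative moisture deduction (13.5%) applies to combine-harvest
GY only and is off by default. Group comparisons use pooled-variance
Student's t by default (matching the trial's analysis label) with a Welch
flag, since group SDs are visibly unequal in practice; the zero-variance
equal-means case resolves to its defined limit t = 0, p = 1.

## Synthetic field generator

The generator emulates the study conditions the pipeline expects:

* **Collections** of 51 (default) or 42 varieties × 6 stages, with one
  planted high-NUE variety. Baseline varieties cycle through three archetype
  trajectories (baseline/lush/sparse, N% declining from ~3.2 to ~1.2 across
  stages) plus per-stage Gaussian jitter (sd 0.08); the high-NUE archetype
  (3.4, 3.3, 3.1, 2.9, 2.6, 2.2) is then *enforced by construction* to
  satisfy the screen on true values — vegetative values clipped into the
  45–90th percentile of the others, FHS/MRS raised above the collection
  maximum, decline rate capped below the median. These numeric defaults are
  qualitative archetypes of rice nitrogen-dilution curves, config-overridable,
  and not measurements.
* **Plot reflectance** inverts Model I: the larger quadratic root maps true
  N% ∈ [0.58, 14.5) to NDRE ∈ [0, 1); a fixed smooth canopy spectral template
  is scaled so the 720/800 nm pair realizes that NDRE. At tillering the
  canopy is convexly mixed with a water spectrum (ρ800 = 0.02, ρ720 = 0.01,
  default fraction 0.3), pulling TS points off the Model-I curve exactly as
  the tillering exclusion presumes.
* **Scenes** place six calibration panels and the plot grid on a soil
  background; DN = (ρ − Offset)/Gain per band plus i.i.d. Gaussian noise
  (no spatial correlation — the simplest model that exercises aggregation).
  DNs are float by default; a flag quantizes to the 10-bit range.
* **Ground measurements**: chemical N% = truth + N(0, 0.05); SPAD affine in
  N% (12·N% + 8); the N-pen reading floors at 2% N, so low-nitrogen stages
  cluster at the floor; LAI comes from the trajectory.
* **Dosage trial**: 2 varieties × 4 N treatments (0/120/180/240 kg/ha) × 30
  plants, trait means echoing a typical high-NUE-hybrid vs check contrast
  (per-plant yield 38.5 vs 20.6 g at 0 kg/ha, seed setting 92% vs 56%);
  counts are continuous draws so zero-noise means reproduce the
  configuration exactly.

Every generator is a pure function of (config, seed); scenes are
byte-reproducible. What the generator does **not** emulate: radiative
transfer (PROSAIL-class canopy physics), illumination/BRDF and shadow
effects, spatially correlated noise, co-registration error, or genetic
structure among varieties. Passing tests therefore demonstrate the
pipeline's correctness and its ability to recover planted structure under
the stated noise model — not field-level accuracy on real imagery.

## Numerical choices and problem sizes

Quadratic/linear fits use `numpy.polyfit`/normal equations; the exponential
fit uses `scipy.optimize.curve_fit` (Levenberg–Marquardt, maxfev 20,000) and
raises with iteration diagnostics on non-convergence. Rank-deficiency (≤2
distinct NDRE values for the quadratic, constant NDRE for the exponential)
is an error. The stochastic checks run at the study's design sizes — n = 255
(51 × 5 stages) and n = 252 (42 × 6) for the R² recovery, n = 306 for the
correlation recovery, 200 replicate seeds each, and 100 replicate collections
for the classifier recovery rate — sizes at which the whole suite completes
in seconds.

## Known limitations

* The high-NUE trajectory is enforced, not emergent; classifier recovery
  rates quantify robustness to measurement noise only.
* Trajectory LAI is drawn from templates independent of the Model II
  formula, so end-to-end Model II refits on fully synthetic collections have
  modest R² by design; Model II coefficient recovery is checked on data
  generated by the model itself.
* Pixel rectangles only (no CRS/georeferencing); rasters are plain multiband
  TIFF with wavelength metadata, layouts plain GeoJSON in pixel coordinates.
* The empirical line assumes a stable linear sensor between panels and
  plots; vignetting, atmosphere and BRDF are out of scope.
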