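# Methods

`hypertrait` implements an end-to-end analysis for predicting and spatially
mapping gravimetric water content and nitrogen content in potted wheat from
dual-camera hyperspectral images, together with a synthetic scene generator
that stands in for glasshouse image data.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic testbed
does and does not demonstrate.

## The measurement model

A line-scanning camera records digital numbers (DN).  With a dark-current
frame `I_dark` and a white-reference frame `I_white` acquired under the same
settings, reflectance is

    R = (I_raw − I_dark) / (I_white − I_dark).

Elements where `I_white = I_dark` are undefined; they propagate as NaN and
are excluded band-wise from later averaging (clipping them would bias mean
spectra; the count is logged).

Two cameras cover the optical range: VNIR (400–1000 nm, 448 bands) and SWIR
(1000–2500 nm, 288 bands), both with uniformly spaced band centers by
default.  Per-plant mean spectra from the two cameras are concatenated after
dropping every band whose center lies in the closed overlap interval
[996, 1006] nm.  The cameras have different optical systems, so the fused
spectrum shows an additive jump at the junction; it is left in place by
default (models are trained and validated on equally-jumped spectra, so the
jump carries no bias), and an optional additive splice correction aligns the
first retained SWIR band with a linear extrapolation of the last three VNIR
bands.

Gravimetric water content is `100 (W_F − W_D) / W_F` from fresh and oven-dry
weights; it is scale-invariant in the weights.

## Segmentation

VNIR cubes are segmented by an enhanced vegetation index threshold,

    EVI = 2.5 (R_NIR − R_red) / (R_NIR + 6 R_red − 7.5 R_blue + 1),

with band roles 670 nm (red), 800 nm (NIR), 470 nm (blue), each taken from
the nearest band center (ties toward the lower wavelength).  Vegetation is
EVI strictly above 0.25.  SWIR cubes lack the red edge, so they are segmented
in a "hyper-hue" space: each pixel spectrum is projected onto the hyperplane
orthogonal to the all-ones vector (removing intensity) and normalized to unit
length.  A one-class SVM (RBF kernel) is trained on known plant-pixel hues —
by default taken from the paired VNIR EVI mask — with `nu`/`gamma` chosen by
a small grid search maximizing held-out inlier rate.  The SVM's native zero
threshold rejects the tails of the vegetation distribution itself, so the
decision threshold is recalibrated at the 1st percentile of the
training-pixel scores; this raised segmentation Jaccard on synthetic scenes
from ~0.87 to ~0.985 without affecting soil rejection (which stays at 1.0).

## Preprocessing treatments

Ten treatments are applied to mean spectra before regression: raw
reflectance (RAW), Savitzky–Golay smoothing (SMO) and first/second
derivatives of reflectance (SGD1/SGD2) or of absorbance log10(1/R)
(ASGD1/ASGD2), all with window 11 and polynomial order 2; multiplicative
scatter correction (MSC) and its extended form (EMSC, 6-degree Legendre
baseline); standard normal variate (SNV, n−1 standard deviation); and range
normalization (NBR).  Numerical choices:

- Savitzky–Golay derivatives are divided by the mean band spacing so they are
  per-nm (physically interpretable); set `per_nm=False` for per-index values.
  Edges are handled by evaluating the terminal window's polynomial
  off-center, preserving spectrum length.
- MSC/EMSC references are the **training-partition mean**, frozen and reused
  for validation samples and pixel-level prediction, so no information leaks
  from the evaluation data into the correction.
- RAW/SMO/SGD1/SGD2 are linear operators; the others are not.  This
  "linearity register" matters for mapping: only linear treatments guarantee
  that the plant-mean prediction equals the mean of pixel predictions.

## Regression and model selection

Five families: PLSR, PCR, ridge-penalized MLR, epsilon-SVR (RBF kernel, cost
50) and random forest (1000 trees).  PLSR/PCR pick 1–10 components by
seeded 10-fold cross-validated RMSEP, taking the smallest count within one
standard error of the curve minimum (an automated, reproducible stand-in for
choosing the lowest point by eye; flat curves resolve toward parsimony).
Ridge scans penalties 0.1–10 in steps of 0.1 with the cross-validation
repeated 10 times and averaged; the path is computed through one SVD per
fold.  All linear fits collapse to a per-wavelength coefficient vector
`beta` plus intercept.

Samples are split into calibration and validation by experimental replicate
(default: the last third of replicate labels), never randomly by sample, so
validation plants are genuinely unseen.

Metrics: RMSE with an n denominator; RPD = sd(y)/RMSE with the n−1 standard
deviation of the evaluation partition's reference values; R² as the squared
Pearson correlation of predictions and reference values.  The ratio form
Σ(ŷ−ȳ)²/Σ(y−ȳ)² is also reported (`r2_ratio`) but can exceed 1 for biased
predictors and is not the headline number.  A constant predictor yields
R² = 0 with a flag, and RPD = sqrt(n/(n−1)) (the two denominators differ).

Wavelength selection is done two ways: (a) keep the top
`round(0.30 × n_wavelengths)` bands by |beta| (ties at the cut toward the
lower wavelength) — 132 bands on a 440-band grid; (b) keep all bands inside
packaged absorption-feature windows (40 nm wide, centered on known water or
nitrogen features; the broad 1400–1450 nm O-H band is kept at its full
stated width).  PLSR is refit on the retained bands and evaluated on both
partitions.

## Distribution maps

Only linear models with a stored preprocessing state can be mapped.  Each
masked pixel spectrum is matched to the model's training grid (nearest band
within 1 nm), passed through the frozen preprocessing, restricted to the
stored wavelength selection, and scored as `beta·x + intercept`.  Only VNIR
cubes are mapped (the SWIR camera's coarser pixels would not overlay), the
background is rendered transparent, values outside the display range are
clipped, and no spatial smoothing is applied.  Maps through non-linear
treatments are produced but flagged.  The pipeline's default map models are
PLSR on RAW spectra for water and on smoothed spectra for nitrogen;
`fit_latent(..., n_components=k)` can override the component count if a map
is visibly noisy.

## The synthetic scene generator

No image data were available to ship, so the generator emulates the data
products and the statistical structure the analysis assumes; all its
parameters live in `SceneParams`/`ChemistryParams` and every draw is seeded.

- **Design**: full factorial of 4 wheat varieties × 9 soil-nutrient
  treatments (a no-nutrient control plus half of the 2⁴ factorial of N
  25/100 mg/kg, P 15/40 mg/kg, K 20/60 mg/kg, micronutrients 5/10 g/150 kg)
  × 2 watering treatments × R replicates; 432 pots at R = 6.
- **Chemistry**: water % drawn around 80 (watered) or 68 (drought) with
  sd 2, so the two groups occupy roughly 72–88% and 64–72%; nitrogen %
  increases linearly in soil N dose (1.5% at zero N, 2.0% at 25, 3.5% at
  100 mg/kg, sd 0.15) — plants in richer-N soil build more chlorophyll and
  protein.
- **Spectra**: a logistic red edge (inflection 715 nm) between a visible
  level of 0.24 and a NIR plateau of 0.56 that declines gently through the
  SWIR, minus Gaussian troughs: chlorophyll absorption at 460/530/670 nm
  with depth 0.030/0.012/0.030 per nitrogen %, and water absorption at
  970/1150/1425/1940 nm with depth 0.0012/0.0018/0.0038/0.0042 per water %.
  Trough depth is *linear* in the trait by construction, so the pot-mean
  spectrum corresponds exactly to the pot-mean trait and regression-recovery
  tests have a known right answer.  Soil/pot background is a featureless
  0.15–0.25 ramp whose EVI sits far below 0.25.
- **Geometry**: a rosette of narrow (3 px) polygonal leaves — deliberately
  thin to mimic the mixed-pixel problem of imaging wheat from above.
  Per-pixel water follows a linear base-to-tip gradient around the pot mean
  with a total drop of 12% fresh mass: wheat leaf tips desiccate and senesce
  first, and this magnitude makes the within-plant signal resolvable above
  the per-pixel noise floor (the minimum-norm unbiased linear estimator
  through the 970 nm trough has ≈1.45% prediction noise at the default
  sensor noise, against a within-plant truth spread of ≈2.8%).
- **Sensor model**: `raw = dark + R (white − dark) + noise` with constant
  dark (100 DN) and white (4096 DN) frames and Gaussian noise of sd 0.01 in
  reflectance units; a per-scene multiplicative gain (log-normal, sd 0.05)
  and additive offset (sd 0.01) emulate the illumination/scatter differences
  between acquisitions that MSC/SNV-type corrections exist to remove; a
  +0.03 additive reflectance offset on the SWIR camera reproduces the
  inter-camera jump at 1000 nm.

What the generator does **not** emulate: radiative transfer (no
PROSPECT-style leaf optics), 3-D canopy structure, self-shadowing or
specular effects, camera co-registration error, differing spatial
resolutions between cameras (both default to the same pixel grid, which is
why the VNIR mask transfers to the SWIR cube in the pipeline), temporal
dynamics, and any genuine biochemical covariance between water and nitrogen.
Passing tests therefore show that the *analysis machinery* is correct and
self-consistent — calibration inverts the forward model, segmentation
recovers known masks, regression recovers programmed traits, maps recover
programmed gradients — not that these accuracies would be attained on real
glasshouse images, where validation R² in the 0.5–0.7 range is typical.

## Problem sizes and degenerate inputs

The packaged study-scale configuration simulates 108 pots (2 varieties × 9
soils × 2 water × 3 replicates) with 48 × 48 px scenes, which keeps a full
run under a minute while leaving ≥ 36 validation samples; the generator
scales to the full 432-pot design.  Degenerate inputs are rejected rather
than silently handled: zero leaf area, empty vegetation masks, constant
spectra under SNV/NBR, exhaustive validation-replicate sets, non-monotone
fused grids, and fewer than 20 one-class training pixels all raise typed
errors.  Spectrally flat SWIR pixels have no hue direction and are classed
background.

## Known limitations

- The hyper-hue construction is the simplest intensity-invariant chromatic
  direction (unit vector orthogonal to the intensity axis); other
  generalized-hue constructions exist.
- `combine_spectra` fuses mean spectra, not cubes; no geometric
  co-registration is attempted.
- The ridge "repeated CV" averages RMSEP over 10 seeded fold assignments;
  other interpretations of repetition are possible.
- Savitzky–Golay filtering assumes an (approximately) uniform band spacing;
  on the fused grid the junction discontinuity makes derivative treatments
  there formally per-mean-spacing, not per-local-spacing.
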