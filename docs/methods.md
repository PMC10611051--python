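# Methods

## Classification model

The pipeline classifies each pixel of an annual, co-registered stack of
linear-power backscatter images as crop or non-crop by thresholding the
temporal coefficient of variation, CV = σ/μ. σ is the *population*
temporal standard deviation (divide by the number of valid dates T, not
T−1): the CV here is a descriptive statistic of the observed season, not
an estimator of a hypothetical longer series, and the population
convention keeps the two-date example [1, 3] → μ=2, σ=1, CV=0.5 exact.
CV is computed on linear power, never on dB values — the logarithm
destroys the multiplicative structure the statistic relies on — and
inputs in dB must pass through `db_to_linear` first.

The physical premise is that field management (tilling, crop growth,
harvest) moves a crop pixel's radar cross section through the season by
multiplicative factors, while forests and most built-up surfaces are
temporally stable, so their temporal CV is dominated by speckle alone:
L-look gamma intensity speckle has CV = 1/√L exactly. Everything above
the speckle floor is signal.

The processing order is fixed and pinned by test: seasonal date
windowing (and removal of screened dates) → per-date enhanced Lee
despeckling → temporal CV → threshold → sieve. Masked pixels (NaN
intensity; μ ≤ 0; fewer than `min_valid_dates` observations) become the
MASK code 255, never silently non-crop.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `cv_thr` | 0.25 | — | operating threshold for 30 m pixels; see a-priori lookup below |
| `looks_L` | 9 | looks | 3×3 multilooked product; exposed because the effective looks of a despeckled product are uncertain |
| Lee `window_size` | 7 | pixels | standard despeckling window for this product scale |
| Lee `damping` | 1.0 | — | conventional damping of the heterogeneous-branch weight |
| `min_valid_dates` | 2 | dates | CV undefined below two observations |
| sieve `min_size` | 20 | pixels | removes classification speckle while keeping ≥2-pixel-wide fields; strict "smaller than" |
| sieve `connectivity` | 4 | — | 4-connectedness; 8 available |
| screening `z_threshold` | 3.5 | robust z | conventional outlier cut on the scene-median series |
| screening `min_relative_deviation` | 0.2 | fraction | see date screening below |
| ROC sweep | 0.0–1.0 step 0.01 | — | CV rarely informative above 1; argmax-J ties break to the smallest threshold (favors crop detection) |

### A-priori threshold lookup

Optimal CV thresholds increase with finer pixels (finer pixels average
less, so both modes sit higher). `select_threshold_apriori` encodes this
as `cv_thr = base + offset·log2(coarse/fine)` clipped to (0, 1]. The
default offset 0.0215 per halving maps the published coarse-resolution
(150 m) value 0.20 onto 0.25 at 30 m. It is a documented heuristic whose
parameters are exposed, not a fitted model: the published reasoning is a
lookup plus "increase for finer pixels", with no functional form given.

### Enhanced Lee branches

With window mean m, window population std s, C_i = s/m, C_u = 1/√L and
C_max = √(1+2/L): homogeneous (C_i ≤ C_u) → m; heterogeneous → m +
W·(center − m) with W = exp(−damping·(C_i − C_u)/(C_max − C_i)); point
target (C_i ≥ C_max) → center unchanged. NaN pixels propagate and are
excluded from window statistics; edge windows shrink (statistics over
the in-image, finite part of the window).

### Date screening

Interference-corrupted dates inflate intensities over large parts of a
scene. The screen summarizes each date by its scene-wide median and
flags robust-z outliers (0.6745·(x−med)/MAD > 3.5). Scene medians over
tens of thousands of pixels are extremely tight, so a few percent of
genuine seasonal drift can reach large robust z-scores; a date is
therefore only flagged when its median also deviates more than 20% from
the across-date center. Gross artifacts move the median by tens of
percent (a gain-10 stripe over 40% of the scene roughly doubles it), so
the guard costs no sensitivity for the artifacts this screen targets.
The screen is advisory: callers exclude flagged dates explicitly via
`build_annual_stack`, mirroring how corrupted dates are removed by
inspection in practice.

## Synthetic scenes

`generate_scene` emulates the statistical structure the classifier
exploits, not radar physics:

* **Speckle**: per-date intensity ~ Gamma(shape=L, mean=μ_t), L=9 by
  default; constant-mean pixels then have temporal CV → 1/√L (verified
  against an independent Monte-Carlo oracle within 3 standard errors).
* **Crop fields**: 30 axis-aligned rectangles (aspect ≤ 4, ≥ 3×3 pixels,
  so every field contains ≥ 9 pixel centers ≈ 0.81 ha at 30 m),
  occupying ~25% of a 160×160, 30 m grid. Each field's temporal mean is
  piecewise-constant with 1–4 multiplicative step changes at uniform
  dates, factors log-uniform in [0.3, 3]. Factors with magnitude under
  ×1.5 (~1.8 dB) are resampled: a management event that changes VH
  backscatter by less than a couple of dB is not a detectable event, and
  modeling events as substantive keeps the CV histogram bimodal the way
  seasonal field management makes it. Weak-event fields still occur
  (single late events), producing the realistic crop/non-crop overlap.
* **Built-up**: constant mean, except a 5% random subset of pixels given
  crop-like event profiles — the double-bounce/parking-lot variability
  that produces classification speckle over urban areas.
* **Forest/background**: constant mean. **Water**: constant low mean,
  masked in the land cover and in the pixel truth.
* **Land cover**: a CDL-style coded raster consistent with the pixel
  truth by construction (crop codes 1/5, forest 141, developed 121,
  water 111, background 176), so binarization can be checked exactly.
* **Dates**: 18 per season by default (~12-day revisit over a ~240-day
  season); mean levels are VH-like linear powers (crop 0.020, forest
  0.030, built-up 0.050, water 0.003, background 0.015).
* **`generative_cv_crossover`**: the midpoint between the median raw-CV
  of crop pixels and of non-crop pixels, recorded so tests can ask
  whether ROC selection recovers the generative separation point on the
  same (unfiltered) CV scale.
* **Interference**: `inject_rfi` multiplies a horizontal stripe (default
  central 40% of rows) by gain 10 on chosen dates.

One integer seed feeds a single `numpy` generator; identical configs are
bit-identical. What the generator does **not** emulate: phenology curves
(events are steps), spatial speckle correlation, terrain and incidence
effects, mixed border pixels (fields are pixel-aligned), real CDL
misclassification. Passing tests therefore demonstrate the pipeline's
statistical machinery and its parameter recovery under the stated model,
not performance on real imagery.

## Sieve semantics

Connected components (4- or 8-connectivity) of class 0/1 smaller than
`min_size` are absorbed into their largest adjacent component.
Deterministic pinned order: eligible components are processed in
ascending size; all components at the current smallest size form one
batch evaluated against the pre-batch labeling; relabel after each
batch. Ties for largest neighbor break to the lowest class value
(logged). Components adjacent only to MASK or the raster edge are
retained — the mask must not bleed into classes. MASK pixels are never
created, destroyed, or counted. `sieve_reference` re-implements the
identical contract by explicit flood fill and serves as the test oracle
(50 random 30×30 grids plus masked variants).

## Assessment conventions

* Pixel centers strictly inside a polygon are kept; centers exactly on
  the boundary count as inside (closed-boundary containment, shapely
  `covers`), deterministic and documented.
* Polygon majority: mean of non-MASK {0,1} labels > 0.5 → crop; a mean
  of exactly 0.5 is non-crop (strict rule). Polygons with no usable
  pixel are flagged and excluded from metrics, and listed in the report.
* Crop polygons → TP/FN; built-up and forest polygons → TN/FP.
* OA = (TP+TN)/N·100; sensitivity TP/(TP+FN); specificity TN/(TN+FP);
  J = sens + spec − 1; Cohen's kappa from the marginals. Metrics with a
  zero denominator are reported as not-available, never 0.
* Pixel-wise agreement between two maps first harmonizes masks (union),
  then scores only commonly valid pixels.
* Reported percentages round half-up to one decimal; across-year
  averages are unweighted means of the (rounded) yearly values,
  re-rounded — matching how such report tables are printed, which is
  what makes the integer count recovery (`recover_count`) exact.
* The maximum of J over a threshold sweep is positively biased under the
  null, so "no real separation" is tested by label permutation
  (`max_j_permutation_pvalue`), not by comparing max-J to zero.

## Problem sizes

Default test and acceptance scenes are 160×160 pixels × 18 dates
(25,600 pixels), with 10 independent seeds for the stochastic checks,
4,000 subsampled pixels × 199 permutations for the null test, and 10⁵
replicate series for the speckle Monte-Carlo — sizes at which the
stochastic acceptance margins (threshold recovery within ±0.1, pixel OA
≥ 90%) are stable across seeds while the whole suite runs in seconds.

## Known limitations

* No reprojection or resampling anywhere: inputs must share the grid
  exactly; misalignment is a hard error by design.
* The CV approach cannot distinguish crop types, and real-world covers
  with crop-like temporal dynamics (parking lots, some pasture) are
  misclassified — the synthetic built-up minority reproduces this.
* The sieve's cascade semantics follow this package's pinned definition;
  other raster toolkits may resolve small-component absorption in a
  different order on pathological inputs.
* GeoTIFF support is deliberately minimal (pixel-scale + tiepoint +
  EPSG GeoKey + nodata); exotic georeferencing (rotated grids, GCPs) is
  out of scope.
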