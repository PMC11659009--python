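# Methods

## Problem and pipeline

Above-ground biomass of winter rapeseed is estimated per field plot from
three complementary descriptions of the canopy, all derived from
co-registered UAV products on a 2.5 cm grid:

1. **Spectral** (vegetation indices). The mean reflectance spectrum of each
   plot polygon is extracted from the hyperspectral cube (400–1000 nm, 150
   bands) and 15 published index formulas are evaluated on it.  Indices are
   computed on the ROI-mean spectrum, not per pixel: the plot is the
   sampling unit of the field design, and averaging before the (mostly
   nonlinear) index formula matches how plot spectra are produced by
   standard ROI tooling.  A per-pixel mode exists for map rendering only.
   Band symbols (R800 …) resolve to the nearest cube band; the lookup
   refuses requests farther than 1.5× the median band spacing, so a dense
   grid serves every index center while sparse stacks fail loudly.
2. **Textural**. Data Range, Variance and Entropy per RGB band, from the
   gray-level co-occurrence matrix (GLCM) computed per pixel over sliding
   windows, averaged over two window sizes (3×3, 5×5) and four offset
   directions (0°, 45°, 90°, 135°).  Conventions: linear quantization to 32
   gray levels; offset distance 1; symmetric accumulation; normalization to
   sum 1; natural-log entropy (a base change only rescales ENT, which is
   immaterial after correlation screening); edge-replicate padding so the
   map keeps the input shape and plot-edge zonal means stay unbiased.
   Data Range is a first-order window statistic (max − min of quantized
   values, direction-free, averaged over the two window sizes): no
   co-occurrence definition of "data range" exists.  First-order
   (occurrence) variants of VAR/ENT are available via `order="occurrence"`
   for compatibility with tools that compute them that way.
3. **Structural**. The canopy height model is DSM − DEM with negatives
   clamped to zero and counted.  Plants are separated from soil by Otsu's
   threshold on the excess-green index (2g − r − b, 256-bin histogram).
   Per plot: PH = mean CHM over plant pixels (cm) — soil pixels are
   excluded so PH tracks what a ruler measures rather than being diluted
   by cover; PR = interquartile range of plant-pixel CHM (a
   median-normalized variant is available); PC = plant-pixel fraction;
   PVM = PC·PH (a pixel-sum canopy volume in m³ is an optional extra);
   CEFR = (mean − bottom-decile mean)/(top-decile mean − bottom-decile
   mean).  Decile *means* rather than single percentiles make the CEFR
   extremes robust to single-pixel spikes; a flat canopy takes CEFR = 0 by
   convention and an all-soil plot leaves it missing.  Zonal statistics are
   taken directly on the dense CHM; no interpolation step is interposed.

## Screening and models

Features are screened by Pearson correlation with observed AGB at
|r| > 0.6, sign-blind (a strong negative correlate such as EXB is as
informative as a positive one), computed on calibration rows only so
feature selection cannot leak into validation.  If no member of a feature
family survives, the single highest-|r| member is retained so every
feature-set × algorithm cell stays defined; the event is logged.
Zero-denominator index values propagate as missing and correlations use
pairwise-complete rows.

Three regressors are compared:

* **DNN** — four hidden ReLU layers of 256/128/64/32 units, dropout 0.2
  after the first hidden layer, Adam (lr 10⁻³, ×0.9 every 100 epochs), MSE
  loss, 600 epochs, batch min(256, n).  Implemented in plain numpy
  (`canopyagb/mlp.py`), which makes training bit-deterministic for a fixed
  seed independent of BLAS threading.
* **RF** — random forest, 80 trees, at most 4 features per split (clipped
  to the feature count with a warning when a screened set is smaller).
* **SVR** — RBF kernel, C = 10, ε = 0.1.  The kernel family is fixed;
  C and ε are defaults chosen for standardized data and configurable.

Features are z-scored with calibration statistics for DNN and SVR; the
target is standardized the same way for those two models (and inverted at
prediction) so the ε-tube and loss scale are meaningful for AGB in kg/ha.
The random forest consumes raw features.

Evaluation follows the trial design: replicate blocks 1–2 calibrate,
block 3 validates.  Plot-level ten-fold cross-validation (all stages of a
plot share a fold) is reported alongside the replicate split, not instead
of it, since the two designs answer different questions (block
transferability vs. average-case accuracy).  Both pooled (all stages, one
model) and per-stage models are produced and labeled distinctly.
Accuracy: R² = 1 − SSE/SST, RMSE = √(SSE/n), rRMSE = RMSE/ȳ of the
evaluated subset.  RF variable importance is impurity reduction,
normalized to sum 1.

## The synthetic scene generator

The generator emulates the field trial the analysis is designed for: a
randomized block of 2 (default; 4 for 60-plot studies) varieties × 5
nitrogen rates (0–360 kg N/ha) × 3 replicate blocks, imaged at three
growth stages.  Per stage, mean AGB per N level is fixed by a preset
(seedling 250–850, bolting 500–1700, early blossoming 1500–5100 kg/ha;
strictly increasing in N), spanning ≈150–6000 kg/ha over the campaign
with right-skewed lognormal plot draws (CV 0.25).  Height follows
PH = 0.25·AGB^0.69 (cm), placing heights in the ≈8–110 cm range; cover
follows a stage-specific logistic in AGB.

Rasters are rendered mechanistically: the canopy of a plot is the
super-level set of a smoothed Gaussian random field thresholded at the
cover quantile (cover is exact up to pixel rounding while retaining
spatial texture); plant-pixel heights are PH times a positive smoothed
field normalized to unit mean (so the plant-pixel CHM mean equals PH
exactly at zero noise); DSM = DEM + canopy ≥ DEM by construction.  Pixel
reflectance is a linear soil/vegetation mixture with sub-pixel mixing from
a slightly blurred plant indicator; the vegetation endmember's NIR plateau
scales with 1 + 0.3·AGB/AGB_max, coupling red/NIR contrast to biomass.
The RGB product is an 8-bit render of the 650/550/450 nm bands.  Heights
are stored in meters in rasters and reported in centimeters in tables.

Plot-level nuisance variability — lognormal soil-brightness (CV 0.06) and
vegetation-endmember jitter (CV 0.06), allometric height scatter
(lognormal, σ 0.25) and cover scatter (logit σ 0.30) — decouples each
feature family from AGB to the degree seen in real campaigns, putting
realized feature–AGB correlations in the ≈0.5–0.9 range and single-family
validation R² near 0.6–0.8 instead of at a ceiling.  These nuisance draws
are recorded in the truth table (`soil_scale`, `veg_vis_scale`,
`veg_nir_scale`) so tests can bound the rendered reflectance exactly.
Additive Gaussian imaging noise (default σ 0.01 reflectance, 0.02 m
height) sits on top.  Identical seeds give bit-identical scenes.

What the generator does **not** model: radiative transfer (no PROSAIL),
BRDF, shadows, view-angle effects, registration error, within-plot
treatment gradients, or lodging.  Passing tests therefore demonstrate that
the pipeline recovers biomass when its structural assumptions hold — not
that it would do so on any particular real campaign.

## Study conditions used by the tests and the acceptance script

* Recovery studies use 60-plot scenes (4 varieties) at low imaging noise
  (σ_refl 0.005, σ_height 0.01 m), ten seeds, median reported.
* The feature-fusion ordering study uses an open-canopy configuration
  (cover logistic (0.0012, 2200), cover ≈0.1–0.7): with a closing canopy
  texture is hump-shaped in biomass, while in the open-canopy regime all
  three families pass the |r| > 0.6 screen, which is the premise of the
  comparison.
* The imaging-noise response is tested with nuisance variability disabled
  to isolate the noise channel, comparing σ_refl 0.005 against 0.08.  Plot
  means average ~600 pixels, so intermediate noise levels are
  indistinguishable at plot level; only the top of the range produces a
  resolvable drop, mostly through the 8-bit RGB bands that drive texture
  and segmentation.
* The acceptance script runs a three-stage campaign (180 plot-stage rows),
  the full 7 × 3 evaluation grid, and reports validation accuracy,
  correlation structure, height-recovery error and RF importance
  concentration.  Problem sizes throughout (24×24 px plots, 150-band
  cubes, 10-seed studies) were chosen so the whole suite runs on a single
  CPU in minutes while keeping every per-plot statistic well sampled.

## Numerical conventions and degenerate inputs

Ties in wavelength lookup go to the lower band index.  Quantization maps
the band maximum to the top gray level; constant bands quantize to zero
and yield zero texture.  A constant excess-green image has no Otsu
threshold and is classified all-soil with a warning.  Zero denominators in
index formulas produce missing values, never exceptions.  CHM negatives
are clamped and counted.  Empty plant∩ROI intersections give
PH = PR = PVM = PC = 0 and missing CEFR; equal decile means give CEFR = 0.
Model fitting refuses missing feature values (rows are dropped upstream
with a logged count) and fewer than five training rows.

## Known limitations

The replicate-based split leaves a single block for validation (20–30
plots), so validation R² carries visible seed-to-seed variance; the
cross-validated metrics are steadier.  The DNN is trained full-batch at
field-trial sample sizes (n ≈ 40–120), where its advantage over the random
forest is modest and configuration-dependent.  The SVR defaults assume
standardized inputs and a roughly unimodal target; heavy-tailed targets
may need ε retuned.  CEFR is undefined for soil-only plots and carried as
missing through screening.
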