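# Methods

This note documents the models and procedures implemented in `hsimoist`, the
assumptions they rest on, the parameters that matter, and the design choices
made where the standard chemometrics workflow leaves room.

## Radiometric calibration

Raw push-broom counts are converted to reflectance per voxel with a white
(100 % reference) and a dark (lens covered) frame:

    R = (R_raw − R_dark) / (R_white − R_dark)

References may be full per-pixel frames or per-band vectors (means over a
reference region); vectors broadcast over the spatial axes. Where
`white − dark ≤ ε` (ε = 1e−9 reflectance units) the voxel is treated as a
dead pixel: the output is set to 0 and the voxel counted in the calibration
summary, rather than propagating an infinity — dead pixels are sensor
defects, not tissue. Values outside [0, 1] (specular highlights, noise
undershoot) are allowed and counted, never clipped, because clipping would
bias downstream means.

**Wavelength grid.** The camera class delivers 151 contiguous bands; the
package defaults to 350–1100 nm at 5 nm spacing, which places all the
features the model uses (430, 560, 595, 695, 780, 980 nm) exactly on-grid.
The grid is configurable everywhere; nothing assumes 5 nm except the default.

## Masking and segmentation

Tissue is identified by a single-band threshold: reflectance at the grid band
nearest 695 nm strictly greater than 0.075. The inequality is strict — a
pixel at exactly 0.075 is background. 695 nm sits in a window free of both
the pigment bands (430/560/595 nm) and the water bands (780/980 nm), so the
rule is insensitive to pigmentation and moisture.

Each piece is divided into 15 segments of equal width along its long axis
(the larger bounding-box extent), widths differing by at most one pixel —
transverse slices, the natural reading of cross-sections of a cylindrical
product. Each segment's unweighted mean spectrum is one sample; the 15
segments of a piece share a block id so they can co-travel through the split.
The pipeline order is fixed: mean first, then absorbance (`A = −log10(R)`)
when the absorbance domain is requested. Reflectance values ≤ 0 (possible
after noisy calibration) are clamped to 1e−6 before the log and the clamp
count reported; failing hard on a single noisy pixel would be brittle.

## Pre-processing

* **SNV** — per spectrum, subtract the mean and divide by the sample (n−1)
  standard deviation. Removes multiplicative and additive scatter exactly
  (`snv(a·x + b) = snv(x)` for a > 0). A constant spectrum has no shape and
  raises an error.
* **MSC** — each spectrum is regressed (OLS with intercept) on a reference
  spectrum and corrected to `(x − b)/a`. The reference is the column mean of
  the *calibration* set, fitted once and frozen; applying a fitted chain to
  prediction rows never touches prediction-set statistics, so there is no
  leakage by construction (and a mutation test asserts it).
* **First derivative** — Savitzky–Golay, window 7, polynomial order 2, scaled
  by the band spacing (units per nm); edges handled by the polynomial fit on
  the one-sided window. Window and order are configuration keys; (7, 2) is
  the common chemometrics default. Order-2 SG reproduces quadratics exactly,
  which the tests exploit as an analytic oracle.
* **Normalization** — unit Euclidean length per spectrum. "Normalization" is
  ambiguous in the field; L2 scaling was chosen because it commutes with the
  linear model's geometry; a min–max variant would be an easy extension.

Chains are ordered lists of these steps; order matters and is preserved
(SNV → derivative differs from derivative → SNV, and both are reported). The
standard comparison grid evaluates five chains — raw, 1st derivative, SNV,
SNV + 1st derivative, 1st derivative + SNV — in both reflectance and
absorbance, ten rows of six metrics. Normalization and MSC are implemented
and usable but not part of the default grid, matching standard reporting
practice for this workflow.

## Kennard–Stone splitting

Selection starts from the pair with the largest Euclidean distance and
greedily adds the sample maximizing its minimum distance to the selected set.
Ties break to the lowest row index, making the selection fully deterministic,
and the first k picks are a prefix of any longer selection. Distances are
computed on the spectra as given (pre-process first if the model will see
pre-processed spectra — selection should see the geometry the model sees).

The default split allocates `floor(n · 2/3)` samples to calibration — for
1023 segment spectra, exactly 682/341. Block-constrained mode runs the
selection on per-piece mean spectra and moves whole pieces, preventing
within-piece correlation from leaking across the split; this is the mode the
pipeline uses by default. Correctness is checked against an exhaustive
brute-force maximin reference on hundreds of random small instances.

## PLSR

Single-response NIPALS: for each component, the weight vector is the
covariance direction `X'y` (closed-form for one response), scores `t = Xw`,
loadings `p = X't/t't`, response loading `q = y't/t't`, and X alone is
deflated. The decomposition is collapsed to coefficients
`B = W(P'W)⁻¹q` and intercept `A = ȳ − x̄'B`, so prediction is a dot product
per spectrum — the form used for pixel-wise maps. X is mean-centered, not
variance-scaled (all bands share units); y is mean-centered. With as many
components as the rank of X the fit equals OLS on centered data, which the
tests assert to 1e−8, and coefficients match an independent reference PLSR
implementation to 1e−6. If a residual covariance direction degenerates
(below 1e−10) the component loop stops early and the model reports the
number of components actually extracted.

**Cross-validation.** "Full cross-validation" is implemented as leave-one-out;
leave-one-block-out is offered as well because LOO leaks within-piece
correlation when segments of the same sausage sit in the calibration set.
Per fold, the chain state (MSC reference) and the centering statistics are
refit on the fold's training part only. RMSECV is accumulated per candidate
component count (default cap: min(20, n−1, bands)); the chosen count is the
first minimum (ties go to the smaller, simpler model). Samples whose held-out
residual exceeds 3·RMSECV are flagged as spectral outliers — a 3-sigma
analogue, configurable — and reported, never removed automatically.

## Evaluation

R² is `1 − SS_res/SS_tot` with SS_tot about the mean of the measured values —
not squared Pearson correlation — so that R² and RMSE are consistent and bias
is penalized; the squared-correlation variant is available for comparison.
All prediction-set metrics use only statistics frozen from calibration. The
measured-vs-predicted scatter is exported with both the regression line and
the x = y reference line in mind (the table carries the set label per
sample).

## Prediction maps

The cube is unfolded to a pixels × wavelengths matrix with stored
coordinates, every masked pixel is pushed through the fitted chain and the
collapsed linear form, and values are refolded by coordinate. Pixels on which
a chain step fails (a constant spectrum under SNV) are set undefined and
counted, not fatal. The default color scale spans the 2nd–98th percentile of
predictions rounded outward to whole percent; a fixed range can be supplied
for cross-image comparability, since maps of different treatments are
usually read side by side. For an empty (purely linear) chain, predicting
the segment-mean spectrum equals the mean of per-pixel predictions; for
nonlinear chains (SNV) this identity does not hold and is not asserted.

## Synthetic scenes

The generator emulates exactly the structure the analysis assumes:

* **Spectral forward model.** Reflectance = linear continuum (0.30 → 0.55
  across the grid) minus Gaussian absorption bands at 430 nm (Soret band of
  heme pigments, depth 0.10), 560/595 nm (oxymyoglobin, 0.06/0.05) and the
  water overtones at 780/980 nm whose depths grow affinely with local
  moisture (0.0020 and 0.0035 depth per % about a 55 % anchor). The slopes
  are free parameters chosen so the reflectance spread over the 45–65 %
  moisture range is visually plausible for this tissue; they are not
  measured constants.
* **Moisture field.** Per-piece means drawn uniformly in 45–65 % — the span
  reported for these products — with a ±3 % linear gradient along the long
  axis by default.
* **Scatter.** Multiplicative factor a and additive offset b vary as smooth
  Gaussian random fields (correlation length 8 px), the pattern produced by
  surface curvature and uneven illumination. Smoothness matters: i.i.d.
  per-pixel scatter would average out of segment means and could not probe
  whether SNV/MSC help, which is the point of including scatter at all.
* **Acquisition.** Raw counts are produced by inverting the calibration
  against generated white/dark frames (white ≈ 0.90 with a gentle band
  roll-off, dark 0.05), plus optional Gaussian sensor noise on the counts.
* **Background** is spectrally flat at 0.02 reflectance, so the 695 nm/0.075
  rule separates foreground exactly in the noiseless limit.
* **References.** Per-segment reference moisture is the truth-map mean over
  the segment plus optional N(0, 0.5 %) measurement noise, emulating
  triplicate oven-drying variation.

What the generator does *not* emulate: radiative transfer and subsurface
scattering physics, casing-specific spectral signatures, specular highlights,
geometric distortion, or temporal drift. Passing tests on these scenes shows
the pipeline arithmetic and its statistical wiring are correct and that
scatter-correcting pre-treatments behave as intended; it does not certify the
accuracy attainable on real sausages, where the spectra–moisture link is far
noisier (field R² values around 0.5–0.6 are typical for intact products).

## Problem sizes and determinism

The default test scene is 6 pieces of 20×96 px at 151 bands (a 144×100×151
cube, ~17 MB as float64) with 90 segment samples — large enough for the
block split and small enough that the full suite runs in seconds. Every
random quantity flows from explicit seeds: scene generation from
`SceneSpec.seed`, reference noise from a caller-supplied generator, and the
acceptance script derives all sub-seeds from its `--seed`. Two runs with the
same configuration produce byte-identical artifacts.

## Known limitations

* Equal-width slicing assumes one roughly convex piece per labelled region;
  touching or strongly curved objects need external instance segmentation.
* The NIPALS implementation targets a single response; multi-response PLS2
  is out of scope.
* Model files serialize the collapsed linear form, not the latent
  decomposition, so score-space diagnostics are unavailable after reload.
* The 350–1100 nm/5 nm grid is an assumption of the camera class, not a
  datasheet value; use the configuration knobs when the instrument differs.
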