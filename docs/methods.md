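# Methods

This note documents the models, conventions and numerical choices behind
osteotherm, and what the test suite does and does not establish.

## Colour representation and conversion

All image processing happens in float64 on unit-scale sRGB.  Conversion to
CIE 1976 L\*a\*b\* follows the standard pipeline: sRGB decompanding (the
IEC 61966-2-1 piecewise curve), the linear-RGB → XYZ primaries matrix, and
the CIE f(t) cube-root transform against a reference white.

* **White point.** D65, the native white of sRGB and the default of common
  flatbed/ImageJ workflows.  D50 is available via Bradford chromatic
  adaptation.  The published matrix constants are 7-digit roundings whose
  rows do not sum exactly to the white point; the rows are renormalised so
  that RGB (1,1,1) maps exactly to L\* = 100, a\* = b\* = 0.  Without this,
  greyscale inputs acquire spurious chroma of ~1e-5 and white exceeds the
  L\* domain by ~4e-6.
* **Scales.** L\* stays on 0–100 and a\*/b\* signed.  The decision
  thresholds (40, 32.5, 75 on L\*; 11, 6.5 on b\*) are only meaningful on
  these scales; an 8-bit 0–255 Lab encoding would silently break them.
* **Gamut.** Lab → sRGB clips out-of-gamut results into [0, 1] and flags
  the clipping; it is never an error, because means of measured bone
  colours are always in gamut while synthetic or corrected colours may not
  be.
* **ΔE.** Colour differences are ΔE\*ab (Euclidean distance in Lab) —
  adequate for chart quality control; no ΔE2000 weighting.

## Chart calibration

Devices are corrected against the 24-patch ColorChecker Classic.  The fit
maps *measured* → *reference* patch colours in **linearised** RGB, because
device crosstalk and gain act on linear signal; fitting companded values
would bake the nonlinearity into the matrix.  The default model is affine
(3×3 matrix + offset), which absorbs scanner black-level offset; a pure
3×3 linear model is available.  Requirements: ≥ 4 patches and a full-rank
design (a grey-only patch set is rejected).  Residuals are reported as
per-patch ΔE\*ab between reference and corrected measurement.  On
noise-free synthetic distortions with condition number < 10 the fit
recovers the inverse map to ≈ 1e-9 (tested at 1e-6).

Reference patch values are the nominal post-2005 sRGB coordinates shipped
as a packaged CSV; the Lab view is derived at load time by the package's
own conversion so the two stay consistent by construction.

## ROI measurement

The measurement convention mirrors the ImageJ workflow the decision model
assumes:

1. **Segmentation** — foreground is the largest connected component of
   pixels with L\* below a background threshold (default 90; Otsu
   fallback), holes filled.  Scans are expected on a white background.
2. **Rim exclusion** — morphological erosion with a disk of radius
   `round(rim_mm · dpi / 25.4)` px.  Default rim width 1.5 mm, the midpoint
   of the 1–2 mm convention; overexposure, chromatic aberration and soot
   deposits concentrate at the outer skirts, and soot in particular mimics
   charring.  Rim erosion is the *only* chromatic-aberration measure — no
   deconvolution.
3. **Mean colour** — mean of per-pixel Lab values (matching ImageJ plugin
   behaviour), *not* the Lab of the mean RGB; the two differ on textured
   samples.  Mean RGB is reported on the 0–255 scale.

A post-erosion ROI below 100 px (configurable) is an error rather than an
unstable mean.  Manual masks (PNG, non-zero = foreground) can be imported
when automatic segmentation is not wanted.

## Decision model

The seven printed rules overlap (cluster 4's "b\* < 11" contains cluster
5's "b\* < 6.5") and say nothing about exact-threshold ties.  The
implementation resolves both with a half-open scheme producing a total,
mutually exclusive partition:

* b\* = 11 belongs to the low-b\* branch;
* within b\* > 11: L\* ≥ 40 → cluster 1, else 2;
* within b\* ≤ 11: L\* < 32.5 → 3; 32.5 ≤ L\* < 75 → 4 if b\* ≥ 6.5 else 5;
  L\* ≥ 75 → 6 if L\* ≤ −25·b\* + 200 else 7.

Ties on the 6/7 line go to cluster 6, the lower-temperature choice —
forensically conservative.  These resolutions are this package's documented
choices, not a published specification.  A\* is accepted and ignored; L\*
and b\* carry the discriminating information.  Thresholds are immutable
defaults but overridable (CLI `--thresholds` JSON) for sensitivity
analysis; they are never re-derived from data.

The partition is verified by brute-force enumeration of the plane
(L\* ∈ [0, 100], b\* ∈ [−128, 127], step 0.1: ~2.55 M points) against an
independent flat formulation of the seven regions, and the classifier's
discontinuity loci are checked to be exactly the published threshold lines.

## Heat maps

Each foreground pixel's Lab is averaged over a `smooth_px` × `smooth_px`
window restricted to the mask (masked normalised box filter; default 5 px)
before thresholding — per-pixel classification is substantially noisier
than the ROI-mean pathway, and unsmoothed single-pixel labels should not be
over-read.  The summary reports per-cluster pixel fractions and a combined
temperature envelope: minimum of the present clusters' minima, maximum of
the maxima, open-ended when cluster 6 or 7 is present.  Maps render to an
indexed PNG with a fixed 8-colour palette (background + 7 clusters).

## Statistics

* **Pearson correlations** with two-sided p from
  t = r·√((n−2)/(1−r²)); zero-variance input is an error, not a NaN.
* **Standardized MLR** via OLS (statsmodels): β = b·σₓ/σᵧ; the
  semi-partial (part) correlation is recovered from the coefficient t
  statistic as sr = t·√((1−R²)/df_resid), which equals the correlation
  between the response and the predictor residualised on the other
  predictors.  With a single predictor β = part = Pearson r (identity,
  tested to 1e-10).  The identity degenerates when R² = 1 (zero residual
  df) — noise-free fixtures are invalid inputs for it.
* **Coding:** medium air = 0 / adipose = 1; age group expands to dummy
  columns.  p-values are raw two-sided at α = 0.05; no multiple-testing
  correction.
* **Empirical cluster ranges** assign every record and report min/max true
  temperature per cluster, retaining unobserved clusters with a flag.

MANOVA-style omnibus testing is deliberately not included; the dataset
loader exposes all factors so any external package can be applied.

## Validation scoring

"Correct" is **range containment**: score 1 iff the known exposure
temperature lies within the assigned cluster's range, with +∞ as the upper
bound of the open-ended clusters 6 and 7.  Two consequences worth making
explicit: a genuinely unheated sample assigned to cluster 1 (minimum 0 °C)
counts as correct, and a 950 °C sample in cluster 6 counts as correct even
though 900 °C was the highest calibrated temperature.  Accuracy is reported
per partition (100·mean score), plus a sample-weighted overall mean
(default) and an unweighted mean of partition percentages; displays round
to integers, computation keeps 0.1 resolution.

## Synthetic data

The generator emulates the *structure* of a heated-bone learning set, not
measured values:

* **Trajectory.**  Piecewise-linear interpolation of temperature-anchored
  mean Lab colours tracing ivory → brownish-black → grey → white.  Default
  anchors at 20, 200, 300, 400, 500, 650, 800 and 900 °C; each anchor is
  placed at least ~2σ inside the decision region of a cluster whose
  temperature range contains that temperature.  The 2σ margin is a design
  rule, chosen analytically: with σ = 2 it bounds per-anchor
  misclassification near 2 %, so anchor subgroups form the separable clumps
  from which threshold models of this kind are cut.  The cluster-7 region
  (wedged between b\* = 11 and the line L\* = −25·b\* + 200) is too narrow
  to hold a 2σ ball at σ = 2, so no default anchor lies there and cluster 7
  appears only through occasional near-line draws.
* **Noise.** i.i.d. Gaussian, σ = 2 Lab units per channel — a small
  within-subgroup spread.
* **Covariate effects.** Duration shifts L\* and b\* by −0.02/min relative
  to a 20-min reference and adipose wrapping adds (+0.5, 0, +0.2) —
  an order of magnitude below the temperature effect, so temperature
  dominates the regressions as it should.  Element, sex and age group are
  assigned uniformly and have **no** colour effect (their null effect is a
  modelling input, so regressions on them estimate pure noise).
* **Design.** Default factorial: 10 temperature levels (20–900 °C),
  durations 10/20/30 min, air + adipose media with adipose capped at
  450 °C (autoignition above), 10 samples per subgroup → 450 records.
  Test-set analogues use 5 per subgroup and durations 5/20/50 min.  These
  sizes keep the full suite and the acceptance script in the seconds range
  while leaving every statistic well-determined.
* **Images.** Elliptical "slices" on a white background with optional
  per-pixel Lab noise, 8-bit quantisation, embedded dpi, and an optional
  contaminated rim of stated physical width (the soot fixture).

What passing synthetic tests shows: the pipeline is internally consistent —
measurement recovers rendered colours, the classifier recovers generating
clusters, scoring recovers designed accuracies.  What it does not show:
performance on real bone.  Real samples have textured, spatially correlated
colour, specular and shadow artefacts, metal/soot tints, and between-device
spectral differences that a 3×3+offset correction only approximates.  The
~99 % accuracies on synthetic test sets are properties of the generator's
clean conditions, not a forensic performance claim.

## Numerical and degenerate-input conventions

* Erosion radius and rim width: physical mm converted at the image's dpi,
  rounded to the nearest pixel; rim 0 mm is the identity.
* Empty ROI, all-background heat maps, non-finite Lab, L\* outside
  [0, 100], zero-variance correlation inputs, collinear designs,
  rank-deficient or < 4-patch calibration sets: all raise typed errors
  rather than returning sentinel values.
* Smoothed Lab at mask borders is renormalised by the in-mask window mass,
  then L\* clipped to [0, 100] to absorb filter round-off.
* All RNG flows through `numpy.random.Generator` seeded explicitly; fixed
  seeds fix generated datasets byte-for-byte.
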