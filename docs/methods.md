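# Methods

## Segmentation model

The pipeline assumes a single-channel 2D image in which organelles are
bright, compact structures over a slowly varying autofluorescent
background, with a known physical pixel size. Processing order:

1. **Background image.** Each pixel whose value exceeds the median of the
   surrounding disc (radius `outlier_radius_px` = 30) by more than
   `outlier_threshold` = 30 grey levels is replaced by that median.
   Because organelles are small relative to the disc, this erases them and
   leaves the background. Boundary handling is edge-including reflection.
   The threshold is in absolute grey levels, so the pipeline is *not*
   invariant to intensity rescaling; inputs are expected on their native
   8/16-bit scale.
2. **Foreground image.** `max(raw − background, 0)` pixelwise. On
   background pixels the difference is exactly zero (they were never
   replaced), so residual noise survives only on organelle pixels.
3. **Blur.** Gaussian, `gaussian_sigma_px` = 1, reflective boundary.
4. **Threshold.** `background_coefficient` × mean of the background image
   over the ROI. The coefficient has no canonical value; the default 2.0
   is a configuration choice that is logged in every result
   (`PipelineResult.threshold`, `background_mean`). The background mean is
   taken over ROI pixels only. A zero background mean degenerates the
   normalisation and raises a warning.
5. **Labelling and filter.** Pixels strictly above threshold inside the
   ROI, 8-connected components (configurable), objects with area strictly
   below `min_area_um2` = 0.15 removed — equality survives. Objects
   touching the ROI border are kept by default (excluding them would bias
   the density, the headline readout); a flag drops them.

**Feret's diameter** is the maximum caliper over the object's pixel-corner
points (corners at `index × pixel_size`, centres at
`(index + 0.5) × pixel_size`), computed as the largest pairwise distance
over the convex hull of the corners. The corner convention gives a single
pixel the diameter √2 × pixel size and matches measuring the longest axis
on object outlines. Degenerate (collinear) corner sets fall back to an
all-pairs scan.

**Density** is reported as objects per µm² of ROI area; `roi_area_um2`
and `n_objects` are reported alongside so any other normalisation can be
recovered.

## Co-localisation

Object centroids are unweighted means of pixel centres, rounded to the
nearest pixel; an object co-localises when that pixel carries a nonzero
label of the other channel. Mask membership, not hull membership, is the
criterion: a centroid of a non-convex object that falls outside the other
channel's mask is a miss. Percentages are computed per direction
(A-in-B and B-in-A) per image, then averaged unweighted across images,
one image per animal; a direction with zero objects is flagged undefined
and excluded from the average rather than contributing 0 or NaN.

## AFM mechanics

The model is a rigid sphere (radius `R_um`, default 5 µm for a 10 µm
bead) indenting an isotropic elastic half-space:
F = (4/3)·E/(1 − ν²)·√R·δ^{3/2}, with ν defaulting to 0.5
(incompressible tissue; configurable). Only approach segments are
handled; adhesion and retract curves are out of scope.

Processing choices, each standard but not uniquely determined by the
measurement itself:

- **Baseline**: a line fitted to the far (lowest-z) 30% of samples is
  subtracted, removing offset and linear drift.
- **Contact point**: the first sample whose force exceeds 3× the baseline
  noise sd for at least 5 consecutive samples; z₀ is the preceding
  sample. On noiseless curves a tiny relative floor replaces the noise
  band, making recovery exact to one sample spacing. This detector is
  biased late by the depth at which the force clears the noise band, so
  the fit co-refines z₀ (below).
- **Bending subtraction**: δ = (z − z₀) − F/k with the cantilever
  stiffness k in N/m (bending in nm is then F[nN]/k).
- **Fit**: the model is linear in E, so the base estimate is the
  normal-equation solution over samples with δ in 10–90% of the maximum
  indentation; by default a contact-point shift (bounded by ±30% of the
  maximum indentation, wide enough to absorb the detector's noise-band
  lag) is then co-fitted with E by trust-region least squares. Degenerate
  inputs (all-zero or negative-signal curves) return `converged=False`
  with the residual, never a silent failure. The rms residual is always
  reported.

## Group statistics

The selection rule is a pure function of three preliminary p-values:
Shapiro–Wilk on each group and a two-sided F-ratio variance test, all at
α = 0.05 (the preliminary α is not separately published; 0.05 is the
conventional choice). If all three exceed α the comparison is an
equal-variance Student t-test — Student rather than Welch, because the
rule has already screened for variance homogeneity — otherwise the
two-sided Mann–Whitney test. Zero-variance groups short-circuit the
F-test (p = 1 if both degenerate, 0 if one). The combined
select-then-test procedure is Monte-Carlo calibrated in the test suite:
under a Gaussian null with n = 20 per group its type-I error stays within
[0.035, 0.065] at nominal 0.05 over 10,000 replicates — a property of the
procedure documented here, not a claim about any dataset.

## Synthetic data: what it emulates and what it does not

Scenes are rotated ellipses (aspect ratio 1–3 by default) with uniform
areas in 0.3–1.5 µm², placed by rejection sampling with ≥ 0.5 µm
edge-to-edge clearance in a 40 × 25 µm (1000 µm²) ROI at 0.05 µm pixels —
Airyscan-like sampling, which also leaves enough pixels per object for
fragmentation geometry. Intensities are background 25 + object amplitude
100 + Gaussian noise (sd 5), clipped at 0 and quantised to integer grey
levels. These defaults were fixed once so that the *default* segmentation
parameters are correctly calibrated for the synthetic material: the
threshold 2.0 × 25 = 50 sits exactly at the half-height of a blurred
object edge, making measured areas unbiased estimates of planted areas.

Fragmentation cuts each object perpendicular to its principal axis at
equal-count quantiles of the pixel projections and erases a band of
`gap_um` (default 0.15 µm) around each cut, guaranteeing piece separation
of at least the gap; an object that cannot yield the requested number of
non-empty pieces (or pieces above an optional explicit minimum) raises an
error naming it — pieces are never silently dropped. Note the default
scene contains objects down to 0.3 µm², whose thirds fall below the
0.15 µm² filter; the segmentation therefore measures fewer than 3× the
baseline count on fragmented scenes, exactly as a size filter must.

Hertz curves are sampled uniformly in piezo height; the indentation at
each height solves δ = (z − z₀) − F(δ)/k by fixed-point iteration to
1e-6 nm, mirroring real AFM geometry so that bending subtraction is
testable against the generator's internal state. Defaults (k = 7.5 N/m,
z-range reaching ≈ 450 nN at ≈ 1 µm indentation, 5 nm sample spacing)
mimic stiff-cantilever force spectroscopy on the worm cuticle.

Deliberately **not** modelled: true membrane reticulation (objects are
convex; real wild-type patterns are branched), Poisson photon statistics
(the threshold-based procedure is insensitive to the noise family at
these signal-to-noise ratios), uneven illumination or autofluorescence
texture, point-spread-function anisotropy, cantilever calibration error,
adhesion and viscoelasticity. Passing tests therefore demonstrate that
the implementation measures what it claims on well-posed material with
known truth — not that the defaults are optimal for any particular
microscope's images.

## Problem sizes and determinism

Test and acceptance runs use one full-size scene pair (1000 µm²,
40 objects) for the fragmentation readout, five 250 µm² scenes for
parameter recovery, 100 small scenes for Feret exactness, 50 force curves
for noisy modulus recovery and 10,000 replicates for the type-I
calibration — sizes at which every check completes in seconds to a couple
of minutes on one CPU. All generators take explicit seeds; identical
spec + seed gives bit-identical images, tables and curves, and a study
rerun with the same configuration writes byte-identical CSV/JSON.
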