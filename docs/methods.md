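# Methods

`phantomtex` quantifies how classical 2-D texture features respond to MRI
acquisition settings, using a fully synthetic stand-in for a nonanatomic
quality-assurance phantom.  This note records the model, the defaults and why
they were chosen, the numerical conventions, and what the synthetic study can
and cannot say about real scanner data.

## Phantom and signal model

The simulated object is a grid of 18 gel tubes (25 mm diameter) plus one
20 mm Gd-DTPA tube inside a 240 x 190 mm field of view, arranged as a central
Gd tube with gel tubes on two concentric rings (radii 28 and 56 mm; minimum
center spacing 28 mm keeps 25 mm tubes disjoint).  Geometry is rasterized by
pixel-center-in-circle membership at the spacing implied by FOV/matrix.

Tube relaxometry is not published for the physical object, so defaults are
chosen to make the object behave like a T1-calibration phantom:

* gel T1: log-spaced ladder 200–2000 ms (so flip-angle/TR changes re-space
  tube intensities);
* Gd tube T1: 686 ms, from R1 = 1/3.0 s⁻¹ + 4.5 (mM·s)⁻¹ × 0.25 mM, a typical
  1.5 T Gd-DTPA relaxivity;
* T2*: 40–100 ms across the gels, 60 ms for the Gd tube; proton density
  10 000 arbitrary units for all tubes.

Noiseless signal follows the spoiled-gradient-echo steady state
S = PD·sin α·(1−E1)/(1−cos α·E1)·e^(−TE/T2*), E1 = e^(−TR/T1).
TR/TE default to 4.78/1.125 ms, the midpoints of the published acquisition
ranges (per-series values are not published).

## Stochastic acquisition model

* **Rician noise.** Independent complex Gaussian noise (SD `sigma_base`,
  default 20 signal units) is added per excitation; magnitudes are taken and
  the NEX magnitude images averaged.  This yields the Rayleigh background
  floor of magnitude MRI and an exact 1/sqrt(NEX) background-SD law.
  The default gives tube SNR between about 4 (longest T1) and 40.
* **Field strength.** 3 T is a ×2 signal gain at fixed noise — first-order
  SNR scaling, sufficient to exercise the contrast.
* **Platform.** Platform B (Siemens-like) applies a Gaussian reconstruction
  filter (FWHM 1.2 px) and a ×1.1 intensity gain relative to platform A
  (GE-like), standing in for vendor-specific image processing.
* **Slice heterogeneity.** Each slice is rendered at a rigid phantom-position
  jitter of SD 0.5 mm per axis.  The study groups pool slices across repeat
  sessions, so slices carry repositioning variability; without it, the
  between-slice variance would be pure noise sampling and every feature —
  including purely structural ones — would reach significance at the study's
  group sizes.  0.5 mm is a half-pixel-scale repositioning/registration
  uncertainty.  Setting `sigma_base = 0` disables *all* stochastic
  components, giving a bit-identical noiseless reference series.

One generator seed drives a whole series; identical configuration plus seed
reproduces identical bytes.

## Preprocessing

1. **Partial-volume correction.**  The iterative optimal (Ridler–Calvard)
   threshold is computed from the intensities inside the contour — T starts
   at the midpoint of the range and is repeatedly replaced by the average of
   the two class means until the update is below 0.5 gray level (sub-integer
   precision is meaningless for integer histograms) or 50 iterations —
   and pixels at or below it are removed from the analysis mask.  The
   correction never adds pixels.
2. **Global normalization.**  The *entire image* is affinely mapped to mean
   250 and SD 30, in floating point (no intermediate requantization).

A caveat that matters for this phantom: a single global threshold assumes two
intensity populations.  With the default T1 ladder the tubes span ~9x in
signal, and the linear-scale threshold settles mid-foreground, classifying
the dimmest long-T1 tubes with the background.  This is the honest behavior
of global optimal thresholding on a multimodal foreground, and it is why

* the automatic whole-phantom contour (`auto_mask`) thresholds
  log(1 + intensity) instead — on the log scale the tubes collapse into one
  foreground mode, and the convex hull then covers every tube regardless of
  doping — while
* the partial-volume step stays on the linear scale, where it correctly
  strips intermediate-gray boundary rims.

In the simulated study one analysis mask (contour + partial-volume
correction, derived from the first slice of the first group) is shared by all
series of a contrast.  Per-series masks were measured to settle in different
inter-tube intensity gaps for NEX 1 vs NEX 4 (thresholds 258 vs 306),
silently moving a whole tube in or out of the compared groups; the compared
groups should differ in acquisition physics, not segmentation.  For real
DICOM input the per-series mask plus per-slice correction path is kept.

## Feature definitions

41 core features plus three report extras, per slice-ROI:

* **Histogram (12).**  Mean, median, SD, geometric and harmonic mean (on
  values shifted to ≥ 1 if nonpositive values occur), 4th central moment,
  IQR over the masked intensities; entropy in bits over the 256-bin
  quantized histogram; "range", "2nd STD", STD5 and STD9 as ROI averages of
  local statistics (3x3 max−min; population SD over a horizontal pair, a
  plus-cross, and a 3x3 box).  The local-neighborhood reading follows the
  footnoted "5-/9-neighborhood standard deviation" naming; exact footprints
  are a judgment call.
* **GLCM (5).**  Distance-1 symmetric co-occurrence matrices in four
  directions, normalized then averaged; contrast, correlation, energy (ASM),
  homogeneity, and entropy with the natural log (−Σ p ln p).
* **GLRL (11).**  Standard Galloway/Tang run-length statistics (SRE, LRE,
  GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE) with 1-based gray
  index, computed per direction and averaged over the four directions.
* **GLGM (4).**  Mean, variance, skewness and kurtosis (standardized 3rd/4th
  moments, kurtosis non-excess) of 3x3 Sobel gradient magnitudes over ROI
  pixels with a full 3x3 in-image window.
* **Laws (9).**  Mean squared response of the nine 3x3 masks from the outer
  products of L3 = [1,2,1], E3 = [−1,0,1], S3 = [−1,2,−1] (the 3x3 triple is
  the family yielding exactly nine masks).
* **Extras (3).**  `mean_skewness`/`mean_kurtosis` are the skewness/kurtosis
  of the ROI intensity distribution; `mean_laws` is the sum of the nine Laws
  energies (matching the magnitudes reported alongside them).

Conventions: gray levels come from linear min–max binning of the masked,
normalized intensities into G = 256 levels (configurable); pairs and runs
count only pixels inside the mask; a constant ROI yields GLCM correlation
NaN with a warning, likewise GLGM shape moments at zero gradient variance.
Every GLCM/GLRL/GLGM/Laws value is verified against an independently coded
per-pixel brute-force implementation to 1e-10 in the test suite.

## Statistics

Each contrast is one family of 41 tests.  Two-level contrasts use the
pooled-variance (Student) two-sample t-test, two-tailed; the seven-level
flip-angle contrast uses one-way ANOVA (the source analysis reports a single
P per feature across the seven levels without naming the multi-group
procedure; ANOVA is the natural choice and reduces to F = t² for two
groups).  P-values are corrected per contrast with the Benjamini–Hochberg
step-up (q(i) = min over j ≥ rank(i) of m·p(j)/j, capped at 1), implemented
directly from the definition and cross-checked against both a brute-force
oracle and `statsmodels` in the tests.  Significance is declared at
Q < 0.05.  The statistical unit is the slice; within-series correlation is
deliberately ignored, as in the original analysis.

## Simulated study and problem sizes

The default study reproduces the four assessments at the published group
sizes (slices per group): magnet strength 1.5 T (80) vs 3 T (61) at
256 x 192; flip angle 2–30° (36 each, 44 at 30°); NEX 1 (36) vs 4 (44) at
256 x 160; platform A (83) vs B (36) at 256 x 160.  The acceptance suite
runs the NEX assessment at the full 256 x 160 matrix, 50 replicates
(~2.5 s each); unit tests use smaller matrices (down to 48 x 36) where only
mechanics are exercised.

Under this generator the NEX effect is carried by entropy/uniformity
features (histogram and GLCM entropy, energy, homogeneity), run structure
(SRE/LRE/GLN/RLN/RP), local SD/range statistics, and gradient magnitudes —
all with q-values many orders of magnitude below 0.05 — while the
low-gray-emphasis run features (LGRE, SRLGE, LRLGE), which weight dark
structural levels by 1/i² and carry no noise-level term, remain null (as do,
empirically, the smoothed-kernel Laws energies L1 and L2 and `mean_laws`,
whose white-noise terms are a small fraction of their structural energy).
The flip-angle and platform contrasts flag most features in simulation:
those parameters genuinely reshape tube contrast (T1 weighting) or the
point-spread function, and with slice variability limited to noise and
repositioning, even modest systematic shifts are detectable at n ≈ 36–83
slices per group.  Real data carry additional inter-session variance that
masks many of these shifts.  Two features the real study flagged for NEX behave
differently here, for an identifiable reason: global normalization and
min–max quantization rescale intensities per image, and a pure noise-level
change inflates the ROI SD and the global SD by nearly the same factor, so
histogram SD and GLCM contrast are near-invariant in this simulation.  In
real data, inter-acquisition differences are not a clean noise-level change,
which is plausibly why those features discriminated there.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the contrasts need —
SPGR signal ordering, Rician noise with NEX averaging, platform filtering,
field-strength SNR gain, slice-level repositioning variability — not the
RIDER images themselves.  Printed per-feature table values from the original
study are functions of that specific DICOM data and are out of scope here;
the package accepts a real DICOM directory (`--dicom-dir`) for users who
have it.  No k-space simulation, coil sensitivities, gradient nonlinearity,
B1 inhomogeneity (no inhomogeneity correction is applied either), 3-D
features, or DCE pharmacokinetics.
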