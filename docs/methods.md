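# Methods

## Problem and pipeline

An OCTA en-face angiogram is a square grayscale raster covering a 3 × 3 mm
field at 512 px per 3 mm (pixel pitch 3/512 ≈ 5.86 μm), in which perfused
vessels are bright. The pipeline converts each raster into a binary
perfusion map, decomposes it by vessel caliber, partitions the field into
anatomical sectors, computes two density metrics per sector, and compares
case and control groups statistically. All coordinates use one convention:
pixel centers at integer indices, the fovea at ((N−1)/2, (N−1)/2), rows
increasing downward, 8-connectivity.

## Vessel-map extraction

**Preprocessing.** Optional intensity inversion (for devices that render
vessels dark), contrast balance by mapping the 1st–99th intensity
percentiles to [0, 1] with clipping, then background removal by subtracting
a grey-level morphological opening computed with a square window of 0.25 mm
half-width. Opening was chosen over Gaussian smoothing deliberately: it is
idempotent, so the full preprocess is (near-)idempotent — re-running it on
its own output changes nothing — and it exactly flattens any structure too
thin to contain the window, i.e. all plausible vessels, without biasing
their intensities. A constant raster is returned unchanged with a warning.

**Binarization.** Global Otsu thresholding by default (a pixel is perfusion
iff intensity strictly exceeds the threshold); a fixed threshold is
available for oracle tests. Components smaller than the area of a
25 μm-diameter disk at the image pitch (15 px at 3/512 mm) are removed as
non-vascular speckle.

**Skeleton and caliber.** Topology-preserving thinning
(`skimage.morphology.skeletonize`) gives 1-px centerlines, a subset of the
mask and idempotent. The caliber at a skeleton pixel is 2 × the Euclidean
distance transform of the mask at that pixel, in μm; a centerline pixel
adjacent to background therefore reads 2 × pitch (≈ 11.7 μm), never 0.

**Micro/macro split.** Every mask pixel inherits the caliber of its nearest
skeleton pixel (nearest-feature transform on the skeleton); macrovessels
(MAR) are pixels with caliber > 25 μm, microvessels (MIR) the remainder, so
MIR ∪ MAR = TMI exactly and MIR ∩ MAR = ∅ by construction. The 25 μm cutoff
and its direction are parameters. An empty skeleton under a non-empty mask
classifies everything micro, with a warning.

## Sector geometry

* **Annuli C1–C6**: between the foveal avascular zone (diameter 0.6 mm) and
  the 2.5 mm circle. The radial bandwidth is (2.5 − 0.6)/2 = 0.95 mm; each
  ring has width exactly 0.95/6 ≈ 0.1583 mm (0.16 mm at display precision;
  the exact division is used because six rings of a rounded 0.16 mm would
  overshoot the 0.95 mm band). Ring i covers r ∈ [r_in + (i−1)w, r_in + iw).
* **Hemisphere quadrants SR/SL/IL/IR**: axis-aligned split through the
  fovea; ties on the horizontal line go superior, on the vertical line go
  right.
* **ETDRS quadrants S/I/L/R**: wedges between the ±45° diagonals; each
  boundary ray belongs to the wedge clockwise of it, making rotations by
  90° map wedge memberships exactly.
* Quadrant schemes are computed within the 0.6–2.5 mm annulus by default
  (whole-field optional); the conjunctival layer uses only the whole
  3 × 3 mm ROI. The fovea is assumed at the exact image center (scans are
  fovea-centered); there is no FAZ auto-detection.

Left-eye images are mirrored about the vertical axis before analysis so SR
means the same anatomical quadrant in both eyes; the flip is an involution
and, on even grids with the tie rules above, swaps L/R region memberships
exactly.

## Density metrics

Perfusion density of a region = vessel pixels in region / region pixels.
Skeleton density = (skeleton pixels in region × pitch) / (region area in
mm²), i.e. centerline length per unit area in mm/mm². Length uses the plain
pixel-count × pitch scaling; a diagonal-corrected variant (√2 per diagonal
adjacency) is available behind a flag but is not the default, keeping the
metric a pure pixel-distance scale. Densities are stored as fractions and
converted to percentages only at display. Eye-level records are averaged
into one subject-level value per cell (eye marker `OU`); single-eye
subjects pass through with a warning. Both analysis levels (eye n = 2·subjects,
subject n = subjects) are supported and the level is recorded in every
statistics table, since inter-eye correlation is otherwise unmodeled.

## Statistics

Welch's t-test is the default group comparison (Student's available);
degrees of freedom use the Welch–Satterthwaite formula. Two zero-variance
samples with equal means return t = 0, p = 1 by convention. Pearson
correlation uses the t-transform with n − 2 df and refuses zero-variance
input. ROC analysis computes the empirical curve over all observed
thresholds; the AUC is the tie-corrected trapezoid, identical to
Mann–Whitney U/(n₁n₂), with the pairwise (DeLong placement) value reported
so the 95 % DeLong CI — computed from the variance of the placement values
and truncated to [0, 1] — always brackets it. Marker direction is
auto-chosen so AUC ≥ 0.5 and recorded. The operating cutoff maximizes
Youden's J; LR+ = sens/(1−spec) and LR− = (1−sens)/spec, infinite where the
denominator vanishes. No multiple-testing correction is applied by default
(matching common reporting practice in small OCTA cohorts);
Benjamini–Hochberg is optional.

## Synthetic data

The generator grows a vascular network with seeded biased random walkers:
each walker starts at a uniform position/heading, takes unit steps with
Gaussian heading perturbation (SD 0.25 rad), reflects at the field border,
branches with probability 0.02 per step, and usually terminates on
re-entering perfused tissue (probability 0.5 per step) — a mild
self-avoidance that spreads the network. Each stroke is stamped as disks of
the sampled caliber; calibers come from a mixture straddling the 25 μm
cutoff (retina: 12–60 μm with 20 % above the cutoff by weight; conjunctiva:
10–28 μm, finer and denser, with no FAZ). Strokes accumulate until the
perfusion fraction outside the FAZ reaches the target within ±0.02; because
stroke generation never consults the target, the network for a lower target
is a strict prefix of the network for a higher one at the same seed, which
makes realized density monotone in the target and every output bitwise
reproducible. An unreachable target raises rather than silently truncating.
The image is 0.1 + 0.8·mask with multiplicative speckle
(pixel × (1 + noise·N(0,1)), clipped to [0, 1]) — one-parameter mimicry of
OCTA decorrelation grain.

Cohorts draw per-subject latent (deep-retinal, conjunctival) density pairs
from a bivariate normal with correlation ρ (default −0.9), SD 0.04, clipped
to [0.05, 0.95]; superficial-layer densities are independent draws. The
default group means encode the study conditions of interest: a deep-retinal
deficit and a conjunctival excess of 1.5 between-subject SDs in cases
(0.40→0.34 and 0.30→0.36), no superficial difference, 12 subjects per group,
two eyes each, with left eyes mirrored in construction.

**What the generator does not emulate:** real capillary morphology
(space-filling lobular patterns, flow-weighted intensity), projection
artifacts, motion/defocus artifacts, device-specific gray-level statistics
(the speckle model is a stand-in, not calibrated to any instrument), or
intra-subject inter-eye correlation beyond sharing the latent target.
Passing tests therefore demonstrate correctness of the measurement and
statistics chain on images with known truth — not clinical performance on
patient data.

## Numerical choices and problem sizes

* Achieved-density tolerance fixed at ±0.02 absolute — below the downstream
  recovery tolerance; the walker budget is 200 000 strokes.
* Otsu on the full raster; thresholds compare with strict `>`.
* Boundary ties in sector masks are broken deterministically (superior,
  then right; clockwise for diagonals) so partitions are exact.
* Parameter-recovery checks run on 512 × 512 rasters (10 noise-free, 10 at
  speckle 0.1). The cohort power sweep (100 seeds) runs on the generator's
  latent true densities, where the t-test question actually lives;
  rasterization adds only measurement noise that the recovery checks bound
  separately. The end-to-end correlation-recovery check rasterizes one full
  12-per-group cohort at 160 px — a grid chosen to keep the full suite
  fast while leaving the measured densities' bias far below the latent
  between-subject spread.
* The scan-protocol validator derives only the multiplicative identities
  (positions × repeats, volumes × B-scans × A-scans); it does not enforce
  frame-rate × time consistency, which published protocols often round
  inconsistently.

## Known limitations

Fovea position is assumed exact; no FAZ segmentation, projection-artifact
removal, or 3-D layer segmentation (en-face slabs are taken as given).
The caliber estimate is the centerline distance-transform diameter, which
quantizes at the pixel pitch (≈ 5.9 μm) and therefore classifies vessels
within ~1 px of the 25 μm cutoff by rounding. Eye-level analyses ignore
inter-eye correlation; mixed models are out of scope.
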