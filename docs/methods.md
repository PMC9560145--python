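# Methods

`cocoonct` automates the screening of mason-bee (*Osmia cornuta*) rearings
for parasitoid infestation (chiefly *Monodontomerus* wasps) from clinical CT
scans.  A rearing batch is scanned as a box of densely packed cocoons; each
cocoon contains either one compact adult bee or several small parasitoid
larvae, and the task is to count both kinds per sample and report the
parasitoid rate.  This note documents the models, parameters and design
choices, and what the synthetic tests do and do not demonstrate.

## Segmentation model

The voxel classifier is a 3D UNet with residual units: an encoder–decoder
with skip connections, five depths with 16/32/64/128/256 filters, two 3×3×3
convolutions per depth each followed by batch normalization and PReLU, and a
residual shortcut (identity, or a 1×1×1 projection where shape changes)
around each convolution pair.  Downsampling is stride-2 convolution at every
depth after the first, so a 96³ patch reaches 6³ at the bottleneck.
Upsampling uses transposed convolutions with kernel equal to stride (2): the
exact adjoint of the downsampling, with no overlap and hence no checkerboard
artifacts; the decoder concatenates the same-depth encoder features before
its residual unit.  A 1×1×1 head yields three class scores per voxel
(background, healthy, parasitoid) passed through a softmax.

Classes are modelled as mutually exclusive (softmax) rather than independent
sigmoid channels: a voxel belongs to at most one cocoon, and counting needs
a single class per voxel.  Training minimizes a soft-Dice loss over the two
foreground classes (background excluded; smooth term 1e-5, sums taken over
the whole batch, one global Dice per class) with Adam (default learning rate
1e-4, L2 weight decay 1e-4).  No learning-rate schedule is used.  Gradients
for every layer are hand-derived and verified against central finite
differences in the test suite.

The network is implemented directly on numpy (see `cocoonct.nn`):
convolutions are evaluated by shift-and-accumulate (one BLAS matrix product
per kernel offset), which keeps memory at feature-map size.  This keeps the
whole pipeline importable and trainable on a single CPU; it is not intended
for GPU-scale runs.

A note on translation invariance: because of the stride-2 lattice, the
network is shift-invariant only modulo 2^(depths−1) voxels; on constant
input the interior prediction is periodic with that period rather than
constant.  This is inherent to strided encoder–decoders and irrelevant to
counting.

### Preprocessing and augmentation

Intensities are clipped to the Hounsfield window [−1000, 600] — spanning air
through silk, insect tissue and the plastic box — and mapped linearly to
[0, 1].  Rescaling after clipping is our choice (stabilizes optimization);
the clip bounds are the production values.  Training samples 96³ patches
(32³ in the reduced profile) with a foreground bias (default 0.5: at least
half of the sampled patches contain labelled voxels when any exist), because
a packed-box scan is mostly air.  Augmentation applies random flips
(p = 0.5 per axis), rotations (±15° per axis pair), zoom (0.9–1.1), Gaussian
noise (σ up to 0.05 normalized units) and Gaussian smoothing (σ up to 1
voxel); the transform family is the production one, the magnitudes are
package defaults and fully configurable.  Spatial transforms act identically
on image and labels (labels nearest-neighbour), intensity perturbations on
the image only.

### Inference

Whole volumes are segmented by sliding-window inference: patches at 25 %
overlap, blended with a Gaussian importance map (σ = patch/8), renormalized
per voxel.  Volumes smaller than a patch are padded and cropped back.

## Postprocessing and counting

Probability maps are thresholded at 0.8 — a voxel becomes foreground only if
a foreground class reaches the threshold; if both do, the larger wins, and
exact ties go to healthy (conservative for the rate).  Enclosed air
cavities in the segmentation are then filled with the surrounding class:
cocoon interiors are largely air, so genuine cocoons segment as hollow
shells.  All enclosed cavities are filled, not only those above the
5-voxel bookkeeping size carried in the configuration — filling small ones
too is harmless for counting and makes the operator idempotent.  Cavity
filling is per class, with mixed-boundary cavities assigned the majority
neighbouring class; background connected to the volume border is never
filled.

Instances are separated per class either by plain 26-connected components
or (default) by a distance-transform watershed: seeds are the regional
maxima of the h-reconstruction (default h = 1.5 voxels) of the Euclidean
distance map.  The reconstruction merges maxima separated by saddles
shallower than h, so an isolated cocoon — even when its discrete distance
map carries several equal ridge maxima — yields exactly one seed, while
touching cocoons with a neck deeper than h are split.  Instances smaller than 27 voxels (3³) are discarded as
speckle.  The per-sample record is (healthy count, parasitoid count,
parasitoid rate).

The parasitoid rate is 100 × parasitoid / healthy, displayed with two
decimals rounded half away from zero; this denominator (healthy, not total)
and rounding rule reproduce every per-sample manual-count rate in the
packaged reference table.  A healthy count of zero flags the rate undefined
rather than raising.

## Method comparison statistics

The package ships the published 12-sample table of counts by manual rapid
counting (RC, slice-based), manual volumetric counting (VC, the full-3D
ground truth) and automated counting (AC).  Totals are exact column sums
and total rates are recomputed from summed counts, never averaged across
rows.  The statistical protocol is: Shapiro–Wilk normality screening of the
healthy-count columns; an independent two-sample t-test (pooled variance by
default, Welch by flag) on healthy counts; and the Wilcoxon rank-sum test
on parasitoid counts and rates, using the tie-corrected normal
approximation without continuity correction, with an exact-distribution
option for small samples.  The default alternative is two-sided; on this
table the exact one-sided p-values for RC < VC are 0.004 (parasitoid
counts) and 0.039 (rates), which is how the published significance figures
arise, so the tests here assert the direction rather than a specific
two-sided p.  One known typesetting quirk of the source table is not
imitated: its printed overall AC rate (0.95) is not the 2-decimal rounding
of 100 × 56/5855 (0.96), and three per-sample AC rates are inconsistent
with any rounding of the formula; rates are therefore always recomputed
from raw counts.

## Synthetic phantoms

The phantom generator emulates one compartment of the scanning box: ellipsoidal
cocoons packed on an air background, each a thin shell (12 % of the
semi-axes) whose interior is air except for the content — one solid inner
ellipsoid (scale 0.7) for a healthy bee, or 3–15 small spheroids (radius
10–18 % of the smallest semi-axis) for parasitoid larvae, the count drawn
uniformly because the real per-cocoon brood size is not documented.  Tissue
contrast is a per-tissue mean HU — defaults air −1000, shell −400, bee body
0, larva −100, box wall +100 — chosen to be separable while lying inside
the clip window; the real tissue HU distributions are unpublished, so these
are labelled stand-ins and fully configurable.  The image is optionally
blurred (default σ 0.7 voxels, a point-spread stand-in) and corrupted with
additive Gaussian noise (default 30 HU, a plausible clinical-CT figure).
Labels mark every voxel of a cocoon (shell and interior) with its class;
instance IDs are consecutive; the manifest records exact per-class tallies
and plays the role the full manual volumetric count plays for a real scan.

Packing is rejection sampling with a bounding-sphere overlap test and a
2-voxel clearance.  This is deliberately conservative: it guarantees
separated, fully-in-bounds cocoons and exact ground truth, but it cannot
reach the contact-packing density of a real compartment (where up to ~600
cocoons touch).  Default generation uses 300 cocoons in a 192³ volume at
(0.8, 0.4, 0.4) mm spacing; dataset generation can draw per-volume totals
from the production range 148–606.  Metal sample-number markers are not
simulated — they existed only for manual bookkeeping.

Consequently the synthetic tests demonstrate that segmentation, cavity
filling, instance separation and counting are correct on well-separated,
noise-controlled cocoons with exactly known truth; they do not demonstrate
robustness to touching cocoons, beam hardening, scanner noise spectra or
real tissue variability.  Watershed instance separation (the default) is
what handles merged neighbours when they do occur; plain components
under-count in that case.

## Scaled-down study sizes

CPU-scale checks use a reduced profile — 3 depths, 8/16/32 filters, 32³
patches — on 64³ phantoms of 14 cocoons (parasitoid fraction 0.3, zero
noise and blur, high contrast), 4 training volumes and one held-out volume,
20 epochs at learning rate 3e-3 (the production 1e-4 is a GPU-scale
setting; at desk scale a larger step is appropriate).  Across 3 fixed seeds
at least 2 runs must reach held-out foreground Dice ≥ 0.8 and total count
error ≤ 10 %; in development runs all three seeds pass with Dice ≈ 0.85–0.9
and exact or near-exact counts.  These sizes are the package's own
desk-scale choices; the production-scale accuracy of the method on real
scans is represented by the shipped reference table, not re-derived.

## Numerical and degenerate-input choices

* float32 throughout the network; Adam ε = 1e-8, β = (0.9, 0.999).
* Batch-norm running statistics (momentum 0.1) are used at inference.
* Determinism: every stochastic step (packing, rasterization, sampling,
  augmentation, init, data order) draws from an explicit seeded generator;
  identical config + seed reproduces volumes, losses and CSVs exactly.
* Empty scenes, all-background labels, volumes smaller than a patch, zero
  requested cocoons and zero healthy counts are all defined, tested cases.
* Volumes are stored (z, y, x) with spacing carried per axis; NIfTI is the
  canonical format, DICOM series are read-only with slope/intercept
  rescaling to true HU and explicit errors on missing rescale tags or mixed
  series.

## Known limitations

* The numpy engine is single-CPU; production-scale training (19 annotated
  volumes, 96³ patches, 5 depths) is architecturally supported but slow.
* Bounding-sphere packing cannot emulate contact-dense boxes; phantom
  realism is geometric, not physical (no CT forward projection, beam
  hardening or scatter).
* Parasitoid species cannot be identified from clinical-CT resolution, by
  design of the underlying method.
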