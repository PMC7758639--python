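# Methods

## Scope and data model

The package quantifies multi-channel 3D light-sheet volumes of cleared,
immunolabeled whole mouse pancreata. The universal container is a
`ChannelVolume`: a 3D intensity grid in `(z, y, x)` axis order with a
physical voxel resolution `(dz, dy, dx)` in µm and a channel identity
(insulin, Ki67 or CD45). Coordinates are 0-based voxel indices; all physical
outputs are in µm/µm³, with islet volumes reported in units of 10³ µm³ to
match the size-category definitions, and per-sample totals in mm³
(1 mm³ = 10⁶ × 10³ µm³).

The reference acquisition geometry is 4.8 µm in-plane sampling with a 10 µm
z-step, i.e. a 4.8 × 4.8 × 10 = 230.4 µm³ voxel. The optical z-resolution of
such acquisitions (≈3.8 µm) is finer than the z sampling pitch; volumes are
sums over *sampled* voxels, so the sampling pitch, not the optical
resolution, defines the voxel depth used in volume computation. The choice
is configurable for data acquired at other pitches.

## Segmentation

Two interchangeable backends produce the binary beta-cell (and CD45) mask.

**Classical (reference) backend.** Optional Gaussian smoothing with the
sigma given in µm and converted per axis by the voxel resolution, followed
by a threshold: either a fixed level, or Otsu's level computed on the exact
65,536-bin integer histogram (the level maximizing between-class variance,
ties resolved to the lowest level). The explicit histogram form — rather
than a binned-histogram library call — makes the result exactly
reproducible and exactly testable against an exhaustive search over all
levels. This deterministic backend is the pipeline default because it has
no training inputs and makes end-to-end phantom recovery exact.

**Trainable backend.** A compact slice-wise convolutional encoder–decoder
with skip connections, implemented directly on NumPy (im2col convolutions,
2× max pooling, nearest-neighbor upsampling, sigmoid head), trained with a
soft-dice loss plus a pixel-wise cross-entropy term using Adam. The
cross-entropy term keeps gradients informative early in training, when the
dice term alone is nearly flat and prone to all-background collapse; the
dice term drives the overlap that is also the reported validation metric.
The reference configuration mirrors slice-wise semantic segmentation of
light-sheet stacks: four encoding and four decoding levels, intensities
rescaled to [0, 1], a 0.75/0.20/0.05 train/validation/test split that is a
seeded deterministic function of tile order, 350 epochs, and five
augmentation operations (skew, rotation, flip, zoom, elastic distortion)
each applied independently with probability 0.30 in that fixed order. At
inference each z-slice is rescaled, downsampled by a factor of 2 (local
mean), classified, and upsampled back with nearest neighbor to preserve
binarity; slices are processed independently, and training tiles are cut at
the same downsampled scale so train and inference resolutions agree.
Constant slices yield empty predictions by definition. The scaled-down
test configuration (2 levels, 8 base channels, 30 tiles of 32×32, 20
epochs) trains in a few seconds and reaches validation dice ≥ 0.95 on
noiseless synthetic tiles across seeds.

## Islet quantification

The insulin mask is decomposed into 3D connected components; 26-connectivity
is the default (islets are blob-like, and diagonal voxel contacts should
merge), configurable to 6 or 18. Labels are assigned in raster-scan order of
each component's first voxel, making labeling deterministic. Each component
becomes an islet record with voxel count, physical volume, and unweighted
centroid.

Records below the 25 × 10³ µm³ cutoff are discarded as likely nonspecific
signal. Survivors are assigned to small/medium/large/very-large categories
by half-open intervals `[lower, upper)`; a volume exactly at a shared edge
goes to the upper bin. Volumes at or above the top edge (50,000 × 10³ µm³)
are kept in the very-large bin by default — the top edge reads as an
observed maximum rather than an exclusion rule — with a strict mode that
drops them instead.

## Ki67⁺ nucleus calling

The stage order is fixed: (1) slice-by-slice background subtraction by
morphological opening with a disk element (radius 4 voxels by default,
≈ one nuclear diameter at 4.8 µm/voxel; the opening estimates the smooth
local background, and subtracting it is anti-extensive so the result is
nonnegative); (2) local-maximum seeding with a moving 5×5×3 (x,y,z) cube —
a voxel seeds iff it is positive and equals its neighborhood maximum, and a
connected plateau of tied maxima contributes one seed at its
lexicographically smallest (z,y,x) voxel; (3) seeded watershed on the
inverted intensity with voxels at or below the background cutoff (50)
excluded — the cutoff is interpreted on the background-subtracted scale,
since subtraction precedes the watershed in the processing order; seeds
sitting at or below the cutoff are dropped with a warning; (4) a size
filter keeping regions of 4 to 100 voxels inclusive ("smaller than 4" and
"bigger than 100" are removed, so 4 and 100 survive); (5) attribution of
each surviving call to the islet whose label contains its peak voxel — a
single-voxel criterion that stays unambiguous when a region straddles an
islet boundary. Calls whose peak lies outside every islet are recorded with
islet id 0 and excluded from islet counts.

## Inflammation scoring

The CD45 channel is segmented with the same backends as insulin. Each
islet's infiltration is the fraction of its voxels that are CD45⁺; an islet
with at least 5% CD45⁺ volume is inflamed (the boundary value counts as
inflamed). Per-bin inflamed percentages are reported as 100 × inflamed /
islets-in-bin; a bin with no islets reports an undefined value, not 0%.

## Statistics

For a two-group design over per-sample summaries:

* **Percent change**: 100 × (treated − reference)/reference on group means,
  kept at full precision internally and rounded only for display.
* **Unpaired t**: classic pooled-variance Student's *t* (not Welch), df =
  n₁+n₂−2. Zero pooled variance with equal means returns t = 0, p = 1.
* **Hotelling T²** for the correlated per-bin (count, volume) pair:
  T² = (n₁n₂/(n₁+n₂)) d′S⁻¹d with pooled covariance S, converted to
  F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2)) on (p, n₁+n₂−p−1) df. With p = 1 this
  reduces exactly to the squared t statistic. No correction across the four
  bins is applied.
* **Mixed 2×4 ANOVA**: treatment between subjects, size category within.
  Sums of squares follow the classic cell-means decomposition
  (between-subjects: treatment vs subjects-within-groups; within-subjects:
  category and category×treatment vs category×subjects-within-groups).
  With 7 subjects per group and 4 categories the uncorrected dfs are (1,12)
  for treatment and (3,36) for category and interaction. Degenerate inputs
  (zero error variance, missing cells) raise rather than imputing.
* **Sphericity**: Mauchly's W on the covariance of k−1 orthonormal
  (Helmert) contrasts, pooled within the two groups (the standard treatment
  for mixed designs); χ² approximation with the Bartlett correction factor
  on the pooled error df. The Greenhouse–Geisser ε is (Σλ)²/((k−1)Σλ²) over
  the contrast covariance eigenvalues. The GG correction multiplies both
  within-subject dfs by ε, applied only when Mauchly's p < 0.05. The
  p-value uses the first-order χ² approximation; tools that add the
  second-order expansion term report slightly different Mauchly p-values,
  while W, χ², df and ε agree to machine precision.

A note on GG conservativity: for effects with small p the ε-shrunken dfs
always increase the p-value; for clearly null effects (F < 1) the tail
probability can move in either direction. The property tests assert
conservativity in the regime where the correction matters (raw p ≤ 0.10).

## The phantom generator

The generator emulates the *geometry and contrast structure* of a cleared
whole-pancreas acquisition, not its optics. Islets are non-overlapping
axis-aligned ellipsoids with aspect ratios sampled in [0.7, 1.4]
(normalized to preserve the equivalent-sphere radius), placed by rejection
sampling with a guaranteed surface clearance (default 25 µm) so that
connected-component recovery is unambiguous; equivalent radii follow a
log-normal law (median 40 µm, log-sd 0.6), spanning all four size
categories, with an optional stratified mode that cycles islets through the
categories in a small-heavy 3:3:1:1 mix (real pancreata are dominated by
small and medium islets, and very large islets could not physically pack at
equal proportions). Rasterization is voxel-center-exact and the truth
records the rasterized voxel count, so recovery checks compare integers,
not approximations.

Ki67⁺ nuclei are planted at voxel centers inside islets with a minimum
mutual separation (default 6 voxels) and rendered as Gaussian blobs with
σ = radius/2. The rendering operating point — amplitude 120 counts above
background, apparent (PSF-blurred) spot radius 14 µm — is derived from the
fixed nucleus-calling constants: the watershed cutoff (50) must sit between
the noise floor left by the opening (≈1.6σ_noise, i.e. ≈19 counts at the
10%-of-amplitude noise level) and the spot peak, and a noiseless spot must
rasterize safely inside the 4–100 voxel size filter (it covers ≈9 voxels).
CD45 infiltration draws a per-islet volume fraction from a Beta(2, 8) law
and marks that fraction of islet voxels CD45⁺, filling a peripheral shell
(15 µm) first and speckling the interior with the remainder — matching the
observation that leukocytes accumulate at the islet periphery.

Noise is additive Gaussian (off by default; Poisson optionally), clipped
and quantized to 16 bits. All randomness flows from a single integer seed
through one generator, so identical seeds give bit-identical volumes and
truth.

**What the phantom does not model** — and hence what passing tests do not
show about real data: anatomical pancreas and lobular shape, vasculature,
light attenuation and scattering in cleared tissue, depth-dependent PSF
anisotropy, autofluorescence texture, antibody penetration gradients, and
touching or merging islets (non-overlap is enforced; merging behavior is
exercised separately at the labeling layer). Recovery being exact on
phantoms demonstrates the correctness of the measurement chain, not the
segmentation difficulty of real stacks.

## Numerical choices and degenerate inputs

* Thresholds binarize with strict `>`; a fixed threshold at half the islet
  intensity recovers a noiseless phantom's rasterization exactly.
* Binning intervals are half-open `[lower, upper)`; the brute-force
  interval scan and the vectorized search agree on randomized volumes.
* Dice of two empty masks is defined as 1 (identical segmentations).
* A constant volume cannot be intensity-rescaled (error); a constant slice
  predicts an empty mask in the trainable backend.
* An empty seed list is an error for the watershed; a seed at or below the
  cutoff is dropped with a warning, not an error.
* Islet tables serialize volumes at full float precision so that re-binning
  after a CSV round trip is unchanged; unmeasured stage fields are written
  as empty cells, never zeros.

## Problem sizes in the test and acceptance runs

The recovery phantom is 128×256×256 voxels (≈1.3 × 1.2 × 1.2 mm at the
reference geometry) with 50 islets and ~200 nuclei; unit-test phantoms are
64×128×128 with 8 islets. The scaled-down segmenter training uses 30 tiles
of 32×32 at 2 levels for 20 epochs. These sizes were chosen so the full
suite and the acceptance script each complete in minutes on a single CPU
while still exercising every stage at realistic islet geometry.
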