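# Methods

This note documents the models, parameter choices, numerical
conventions, and known limitations of `dendroquant`.

## Brightness normalization and projection

Intensities are mapped to [0, 1] by dividing by the dtype maximum
(2⁸−1 or 2¹⁶−1), never by the image's own maximum: a fixed brightness
threshold such as 0.4 is only meaningful on an image-independent scale.
Bit depth defaults to 16 when not declared. Maximum-intensity
projection takes the per-pixel maximum over all optical sections,
independently per channel; it is idempotent and commutes with monotone
rescaling. Stacks use (z, row, col) axis order with channels stored
separately, avoiding multi-channel TIFF dialect ambiguity. Coordinates
are 0-based and pixel-centered; masks are boolean with white = 255 =
included.

## Observation paths and skeleton length

ROIs are grown from 1-px skeleton curves by Euclidean-disk dilation:
the mask is every pixel at distance ≤ r from the curve (computed via an
exact Euclidean distance transform), clipped at image borders without
error. For a straight curve this reproduces a band exactly 2r + 1 px
wide; drawing-tool "grow selection" implementations vary in their
structuring element, so the Euclidean disk is the documented contract
here. The default radius is 95 px.

Skeleton length sums chain steps between adjacent curve pixels —
1 px orthogonal, √2 px diagonal — counting each adjacency once and
skipping any diagonal adjacency that is bridged by an orthogonal curve
pixel (otherwise an L-corner would be counted twice). Branches are
summed and loop edges counted once, matching the branch-summation
semantics of standard skeleton-analysis tools. Length is invariant
under 90° rotation and reflection. A single pixel has length 0.

Pixel size is always an explicit input; the test suite uses the
95 px = 5 µm calibration of the cluster images (0.0526 µm/px) and the
0.066 × 0.066 × 0.2 µm voxel of the spine stacks where relevant.

## Cluster pipeline

Pipeline order: normalize → Gaussian smooth → threshold → label within
ROI.

- **Smoothing** uses an explicitly constructed kernel of side
  `gauss_size` (default 51) and `gauss_sigma` (default 0.8),
  renormalized to unit sum after truncation, convolved with
  edge-replicating borders. At σ = 0.8 the effective support is ≈ 5 px;
  the 51-px side is retained as configured rather than silently
  shrunk. Its purpose is agglomeration: nearby bright pixels merge
  into a single region.
- **Global mode** marks pixels with smoothed value ≥ `global_threshold`
  (default 0.4). Comparisons are inclusive (≥) so the printed
  "minimum brightness" value itself qualifies.
- **Adaptive mode** marks pixels with value ≥ local-window mean +
  `offset`. The window is the (2·`window_half`+1)² rectangle centered
  on the pixel (default half-width 10), clipped at borders with the
  mean taken over available pixels only (implemented with an integral
  image, since library uniform filters pad rather than clip). The
  window includes the center pixel. Because a global additive shift
  cancels in value − mean, the adaptive mask is exactly
  shift-invariant; the global mask is not — this is the operational
  difference between the two modes. `offset` has no universal default
  semantics; 0.1 is the package default but should be chosen per
  experimental setup and held fixed within one comparison.
- **Labeling** uses 8-connectivity by default (4 available). Cluster
  area is measured on the smoothed support; the raw image is not
  re-consulted unless `require_raw_bright` is set, in which case a
  global-mode region must contain at least one raw pixel at or above
  the threshold. Areas convert to µm² via the squared pixel size; the
  summary metric is total area per µm of dendrite length.
- **Time series** are divided by the mean total cluster area of the 4
  frames preceding the treatment frame (configurable), so 1.0 means
  "unchanged from baseline".

Smoothing is applied before thresholding in both modes for symmetry.

## Colocalization and ratios

PCC is the standard Pearson coefficient over paired ROI pixels of the
two (projected) channels; at least 3 pixels are required and a constant
channel raises an error rather than returning 0. No background floor is
applied inside the ROI — every ROI pixel enters the correlation.
Membrane and center lines are supplied as pixel coordinates and sampled
at the nearest pixel with no sub-pixel interpolation, matching 1-px
line-mean semantics at this magnification. The membrane/diffuse ratio
averages the two membrane-line means before dividing by the center-line
mean, and is invariant under multiplicative intensity scaling.

## Spine morphometry

Physical (µm³) volume thresholds are authoritative: 0.020 µm³ for
retention and 0.040 µm³ for stubby. Voxel-count equivalents are derived
from the configured voxel volume on demand (at the 0.066 × 0.066 ×
0.2 µm voxel these are ≈ 23 and ≈ 46 voxels). All thresholds are
inclusive ("minimum"/"maximal" read as ≥/≤), and classification order
is fixed mushroom → stubby → thin, so the classes partition the
retained set. A zero neck diameter with a nonzero head makes the
head/neck ratio undefined and raises an error. Manual review is
supported as a CSV export with an override column rather than a GUI.

`measure_protrusions` provides desk-scale measurements on 2D binary
segmentations: protrusions are connected components off the shaft;
length is the maximal Euclidean distance from the shaft surface; the
width profile is the pixel count per unit-distance band (a discrete
chord perpendicular to the outgrowth axis); head diameter is the
maximal band width in the distal half, neck the minimal width between
base and head; volume is pixel area × section thickness (default
0.4 µm). Components touching the image border are excluded with a
warning. This 2D convention is a pragmatic stand-in for full 3D
surface modeling (out of scope) and is validated only against the
synthetic templates described below.

## Synthetic scenes

The generators emulate the features the analyses depend on, not
photorealism:

- **Puncta** are isotropic Gaussian spots truncated at 3σ, with
  σ = r/√(2 ln 2) so the half-maximum support has radius r (default
  4 px); the true area is the pixel count above half-maximum. Default
  peak 0.9 on a flat 0.1 background gives the high-contrast regime of
  well-exposed cluster images. Placement is uniform rejection sampling
  with a minimum center distance (default 2r + 4 px) keeping supports
  disjoint with > 2 px clearance; over-dense requests fail loudly.
- **Backgrounds**: flat, a linear gradient spanning 0.0→0.5 (chosen to
  straddle the 0.4 global threshold so that global thresholding
  provably fails where adaptive succeeds, mirroring uneven confocal
  illumination), or a low-frequency cosine mode.
- **Noise** is additive Gaussian clipped to [0, 1]. Poisson photon
  statistics are deliberately omitted — no noise model is asserted for
  the real images, and the analyses under test are threshold-based.
- **Channel pairs** follow B = ρ·S + √(1−ρ²)·N with S the standardized
  first channel and N independent noise, so E[r] = ρ and ρ = ±1 give
  exact sample correlations.
- **Membrane scenes** are horizontal dendrite bands (interior 0.25,
  1-px edges at enrichment × 0.25; 0.25 keeps enrichments up to 4 on
  scale) with the line coordinates included in the truth.
- **Protrusion tables** sample each spine class's parameter region
  with ≥ 5% margin from every decision boundary, so labels are
  unambiguous; reject items violate exactly one retention filter.
  **Protrusion images** render per-class templates (2-px peg for thin,
  5-px peg for stubby, ball-on-neck for mushroom) with seeded height
  jitter at 0.05 µm/px.

All generators take one explicit integer seed per call
(`numpy.random.default_rng`; no global state) and are bit-reproducible.

What passing on these scenes does **not** show: robustness to
out-of-focus haze, crossing dendrites, photobleaching, chromatic
misregistration, or densely overlapping puncta — real-data regimes the
generator does not model.

## Statistics

Welch's unequal-variance t-test is the "unpaired t-test" default (a
`equal_var=True` flag gives the pooled version). Mann–Whitney U uses
exact enumeration when min(n) ≤ 8 without ties and the tie-corrected
normal approximation otherwise; the Wilcoxon signed-rank against the
hypothetical value 1 is exact for n ≤ 25. Two-way ANOVA uses Type II
sums of squares. Computation is delegated to scipy/statsmodels; the
test suite independently verifies the exact small-sample p-values
against full permutation and sign-flip enumeration.

## Problem sizes

Tests and the acceptance script run on 256×256 scenes, up to 25
puncta, channel pairs of 2,000–100,000 pixels (100 seeds for
correlation recovery; 200 pairs of 10⁴ pixels for the independence
mean), 30-protrusion morphometry scenes, and 1,000-replicate
type-I-error simulations — sizes at which every stochastic check is
stable to well within its tolerance.

## Known limitations

- No automatic dendrite tracing or skeletonization; skeletons are
  inputs.
- 2D protrusion measurement only; no 3D surface modeling or Rayburst
  sampling.
- No Manders coefficients or Costes randomization for colocalization.
- Per-figure threshold offsets are experiment-specific inputs, not
  defaults; the package does not auto-select them.
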