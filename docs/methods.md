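# Methods

`spinalquant` quantifies fluorescent signal in serial-section volumes of
mouse cervical spinal cord by (1) registering each sample's
autofluorescence volume into a common template space, (2) classifying
pixels of the signal channels into probability maps with a random
forest, and (3) summing the warped, thresholded probability maps over
the regions of an annotation volume (cervical level × Rexed lamina ×
hemicord, with motoneuron pools as lamina-9 subregions and named
white-matter tracts). A synthetic phantom generator provides every
stage with exact ground truth, so the whole pipeline is testable
without any imaging data.

## Coordinate and data model

Volumes are Z×Y×X voxel grids; Z increases rostral→caudal in section
order, Y is dorsoventral, X mediolateral. Voxel sizes are carried in
micrometres everywhere; the b-spline control-grid spacing is configured
in millimetres and converted at the registration boundary. The midline
is a declared X column index: the left hemicord is x < midline, the
right x ≥ midline. Region ids are positive integers (0 = background)
assigned deterministically by the ontology builder in a fixed traversal
order (level, lamina ascending, pools, tracts; left before right).
Lamina 6 does not exist at C1–C3 and the builder enforces this.
Ipsi/contralateral is never stored in region ids; it is derived at
aggregation time from per-sample injection-side metadata.

## Registration

The sample→template alignment is a chain of rigid (6 dof), affine
(12 dof) and free-form b-spline stages. Each stage optimises Mattes
mutual information (32 histogram bins, 10% random coordinate sampling
reseeded from the run seed) over a multiresolution pyramid
(6 levels by default; shrink factors capped so the coarsest image
keeps ≥4 voxels per axis). Rigid and affine use regular-step gradient
descent with parameter scales estimated from physical shifts; the
b-spline stage (~650 parameters at the default 1×1×1 mm final grid)
uses L-BFGS-B over a short two-level schedule, which converges in
seconds where gradient descent at full depth does not terminate in a
useful time on one CPU. All transforms map fixed-space (template)
points into moving-space (sample) points — the resampling convention —
and stages compose right-to-left (the last-fitted stage is evaluated
first). Intensities and probability maps are resampled linearly,
label volumes with nearest-neighbour; out-of-frame voxels fill with 0,
matching the zero padding of short stacks.

Landmark refinement solves the affine minimising the summed squared
distances between paired fiducial points in closed form (least
squares on homogeneous coordinates; ≥4 non-coplanar pairs required)
and reports the residual RMS. The fitted transform maps atlas points
to sample points, so it can be inserted directly into a resampling
chain; by default it is prepended as an additional stage, after which
the b-spline can be re-run. Registration accuracy on phantoms:
a rigid offset of 30 voxels / 10° is recovered to well under one
in-plane voxel; anisotropic scale errors after the affine stage are
below 1%.

## Pixel classification

Sections are classified pixelwise by a random forest (100 trees by
default, unlimited depth, fixed seed) over an interactive-segmentation
style feature bank: raw intensity plus, at each scale
(0.7, 1.0, 1.6, 3.5, 5.0 px by default), Gaussian smoothing, gradient
magnitude, Laplacian of Gaussian, and the eigenvalues of the Hessian
and of the structure tensor. Multichannel sections (signal +
autofluorescence) concatenate per-channel features; the
autofluorescence channel is what lets the forest separate gray from
white matter. Training uses sparse brush-style labels on up to five
representative sections per sample, one model per cohort.

Class probabilities export as 8-bit maps (value v ≙ probability
v/255). Vote fractions are scaled by 255 and floored, which keeps
every per-voxel sum over k classes within [255−k+1, 255] — the floor
(rather than round) guarantees the sum never exceeds 255. The
denoising threshold τ (default 86) zeroes voxels below τ and keeps
the original value at or above it; it is intensity-preserving because
quantification sums map intensities, not a binary mask. τ applies to
the signal classes only; tissue/background maps are for visualisation
and are excluded from quantification.

## Quantification and statistics

The quantification unit is the summed probability-map intensity of a
signal class within a region, per sample — an exact integer
accumulation, so per sample and class the region entries sum to the
total thresholded intensity inside the annotated mask (asserted in
tests). Normalisation modes: `total_signal` (per-sample grand total)
and `axon_reference` (classified axon signal in white-matter regions,
a labeling-efficiency proxy); the mode is recorded in the output.
Aggregation views sum over level / lamina / hemicord / pool, with
percentage views normalised to 100 within declared axes.

Group comparisons use the tie-corrected Kruskal–Wallis test with
Dunn's pairwise z post hoc (pooled mid-ranks, tie-corrected pooled
variance, two-sided normal p) and Benjamini–Hochberg FDR applied
across the broadest family — all regions × all pairs — which is the
conservative choice when the family is otherwise unspecified. When
all pooled values are identical the rank variance is zero and the
defined result is H=0, p=1. Fold changes are
log10((mean A + ε)/(mean B + ε)) with pseudocount ε = 1 intensity
unit by default, since sparsely innervated regions contain exact
zeros; fold changes may be computed on raw or per-sample-normalised
values (raw by default). Laminar clustering is agglomerative with
Euclidean distance and complete linkage, matching the defaults of the
heatmap tooling this analysis style comes from; dendrograms export as
Newick text.

## The phantom generator

The generator emulates the study conditions end to end. Per section,
the cord outline is an ellipse whose semi-axes vary smoothly along Z
with a cervical-enlargement bump; gray matter is a butterfly-shaped
union of dorsal-horn, ventral-horn and central ellipses, mirror-
symmetric about the midline by construction. Laminae 1–9 partition
each hemicord's gray matter as dorsoventral bands with fixed relative
thicknesses; lamina 10 is the pericanal zone; motor pools (if
configured) carve mediolateral blocks out of lamina 9; white matter
splits into a dorsal-column tract and the remaining ventrolateral
white. Autofluorescence is brighter in gray than white by a
configured contrast (0.6), with a bright rim just inside the tissue
border and optional smoothing.

Signal deposition: puncta are isotropic in-plane Gaussians (σ
1–2 px, amplitude jittered 50–100%) with per-region Poisson counts at
configured densities (expected puncta per 1000 voxels; the default
profile is densest in laminae 5 and 7 contralaterally with ~5%
ipsilateral signal). Axon-like structure is a set of Gaussian-profile
tubes following quadratic Bézier paths down the dorsal column.
Soma-like blobs (σ 2–3 px) are placed inside lamina-9 regions. Blob
centres are drawn from the region mask eroded by about one blob
radius (2.5σ for puncta, σ for somas) so a deposit lies essentially
wholly inside its recorded region: per-region truth sums are then
clean ground truth, and somas sit inside their pools as motoneuron
somas do. Truth records per-region pre-noise intensity sums (their
total equals the masked deposit exactly), per-voxel class labels,
soma placements and all deformation parameters. Noise is a
Poisson-like shot component (gain 10) plus additive Gaussian
(σ 30) over a constant offset.

Per-sample variability is a known rigid (±8 voxels, ±4°) + affine
(±4% scale, ±2% shear) + smooth elastic deformation. The elastic
component is a random b-spline on a coarse 2×2×2 control mesh
(~1.3 mm spacing at the default grid) with ±2-voxel in-plane
amplitude: inter-animal anatomical variation is smooth at the
millimetre scale, and a finer mesh would put warp content below the
1 mm recovery grid, making it unrecoverable by construction. All
outputs are pure functions of (config, seed).

What the phantom does not model: optical PSF and tiling artifacts,
vascular/bone structures, intensity inhomogeneity across sections,
dendrites crossing the gray/white boundary, and anatomically accurate
lamina geometry. Passing tests therefore demonstrate the pipeline's
mechanics — transform recovery, classification separability at
realistic contrast, exact accumulation, statistical calibration — not
performance on real tissue.

## Problem sizes and numerical choices

The default working grid is 50 sections × 256 × 256 at 10 µm in-plane
and 60 µm section spacing, the scale at which a full registration
runs in about a minute on one CPU. Transform-recovery validations run
at this default size. The end-to-end cohort validation (two groups of
three samples, 10× effect injected into the left lamina 7 — the
densest corticospinal target — and estimated on that lamina's
aggregated signal) runs at 40 × 224 × 224 with 50-tree forests, and
the five-phantom template-construction check at 24 × 160 × 160 with
rigid-only offsets — sizes chosen so the full validation suite
completes in minutes while leaving every algorithmic setting (metric,
sampling, τ, pyramid schedule) at its default. The cohort grid is the
smallest at which probability-map quantification stays in its linear
regime for a tenfold effect: each punctum claims a roughly
FWHM-sized patch of map area, so a region must hold an order of
magnitude more voxels than the patched area of its densest condition
before summed map intensity grows proportionally with deposit count.
Degenerate inputs are defined rather than fatal where a convention
exists (blank sections recenter with zero shift; identical-value
groups give p=1); genuine contract violations (empty volumes, grid
mismatches, unknown regions, coplanar fiducials, zero normalisation
denominators) raise errors naming the offending input. Determinism:
every stochastic stage consumes an explicit seed; metric sampling,
forest training and phantom generation reproduce bit-identically for
a fixed seed.

## Known limitations

- Mutual-information registration assumes overlapping content and a
  roughly centred initialisation; the recentering preprocessing step
  and fiducial refinement exist precisely for samples that violate it.
- The b-spline stage's short quasi-Newton schedule leaves a small
  residual deformation (mean ~0.1 voxel on phantoms whose warps live
  at the recoverable scale; warps finer than the 1 mm control grid are
  unrecoverable by construction).
- 8-bit probability maps quantise probability to 1/255 steps; floor
  scaling biases each class down by up to one step.
- Summed probability-map intensity measures classified *area*, not
  fluorescence intensity: once structures are dense enough to overlap
  within a region, the sum grows sublinearly with the underlying
  deposit, compressing large between-group ratios. Effect estimates
  are faithful only in the linear (low fill-factor) regime.
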