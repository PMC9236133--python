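# Methods

This note records the models, estimators, parameter choices and known
limitations behind `gcdyn`, in the order the pipeline runs.

## Synthetic growth-cone movies (`synthgc`)

No public growth-cone time-lapse data exist for the biological setting the
package targets, so the generator provides the ground truth every other
module is validated against.  It emulates a 1-h phase-contrast acquisition
at 30-s intervals (121 frames), 512 × 512 px at 0.25 µm/px by default
(a typical 40× objective; acquisition pixel size is a free parameter).

**Motion model.** The GC base performs a biased random walk: per 30-s step,
the heading is drawn i.i.d. from a von Mises distribution with mean
`heading_pref` and concentration κ, and the step length from a
Gamma(shape = 4) distribution with mean `mean_speed · step_interval`
(positive support, CV = 0.5; only the mean is constrained by the study
conditions, the shape is this package's choice).  Two presets encode the
condition contrast:

| preset | speed (µm/s) | heading | κ |
|---|---|---|---|
| `control_like` | 0.010 | −90° (up) | 4.0 |
| `frda_like` | 0.008 | 0° (horizontal) | 1.5 |

These mirror the *direction* of the published group differences (slower,
less directionally concentrated, horizontally rather than vertically
biased), not their exact magnitudes.  Tracks start at the frame's
bottom-centre, as in the published movies which are rotated so the cone
starts there and grows away from it; a track whose bounding box cannot fit
the frame (with a 3-blob-radius margin for filopodia) is redrawn up to 10
times, then fails loudly.

**Rendering.** Each frame stamps (i) a filled disk of radius
`blob_radius_mean` at the current base (the lamellipodium), (ii)
`n_filopodia` thin spikes fanned ±60° around the current heading, and
(iii) a trailing neurite along the past track.  Two smoothing choices keep
the render biologically sensible: the filopodial fan follows an
*exponentially smoothed* heading (unit-vector EMA, α = 0.25), because a
growth cone reorients over minutes, not within one 30-s step; and the
neurite shaft passes through 5-min waypoints of the track, because
consolidation erases step-scale jinks.  Foreground intensity 0.25 on a 0.9
background plus additive Gaussian noise (σ = 0.05 default); ground-truth
masks are the noise-free binary stamps.  No phase-contrast halo is
simulated — halo robustness is a segmentation concern out of scope here —
and filopodia have no per-filopodium ground-truth dynamics.  Passing tests
therefore demonstrate correctness of the *measurement* chain under a
simplified optical model, not robustness to real phase-contrast artefacts.

**Axon fields.** Intact axons are smooth curvilinear strands (width 2–3.6
px, circularity ≪ 0.5); fragments are ellipses with areas drawn from a
stated range and axis ratio ≥ 0.6, placed disjoint from everything (2-px
gap) and ≥ 3 px from the border.  Ground truth (fragmented and total pixel
areas) is recomputed from the final raster, never from placement intent.

## Segmentation (`segment`)

The preprocessing recipe follows the published axon-chamber pipeline:
median despeckle, rolling-ball background subtraction on the inverted
(light-background) image, contrast enhancement (clip 0.3% saturated pixels
split between tails, rescale, equalize), then Otsu thresholding on a
256-bin histogram with foreground = pixels darker than the threshold.

Three documented choices:

- A "0.2 px" median radius is degenerate; it is implemented as the
  smallest nontrivial despeckle kernel, a 3 × 3 plus-shaped (4-neighbour)
  median.
- The sliding-paraboloid background is realized with an ellipsoid kernel
  of the stated radius in `skimage.restoration.rolling_ball` (the
  documented grayscale-morphology fallback).
- For growth-cone movies the default configuration (`gc_movie_config`)
  disables background subtraction and equalization.  The 5-px rolling ball
  is sized for thin strands: on a lamellipodium tens of pixels across it
  classifies the blob interior as background and destroys the object.  The
  exact steps of the original semi-automated GC platform are unpublished,
  so the GC default keeps only the steps that are well-posed for large
  blobs (median → contrast rescale → Otsu).

Component selection anchors on a (row, col) point — the component
containing the anchor wins regardless of size, otherwise the nearest one —
and holes are filled.  Movie segmentation anchors frame *t* on the
centroid of frame *t*−1 (the cone moves ≪ its diameter per frame).  On
default synthetic movies the per-frame IoU against ground truth averages
≈ 0.97 (≥ 0.9 required by the regression tests) at noise σ ≤ 0.1.

## Morphometry (`morpho`)

Area is the foreground pixel count × pixel area.  The perimeter estimator
is the length of the marching-squares boundary polygon after resampling to
~1-px spacing and a 5-point circular moving average: the raw staircase
overestimates smooth boundaries by ~5% (rasterized disk circularity ~0.91),
while the smoothed estimator gives a disk ~1.00 and a 100-px square ~0.80
(π/4 ≈ 0.785 ideal).  Circularity is capped at 1.0 (the convention of the
reference measurement tool; the cap is logged at debug level).  Feret's
diameter is the maximum caliper over the convex hull of boundary-pixel
*corners* (an n-px square measures n·√2).  Convex area counts the pixels
of the rasterized hull of pixel centres, so any convex mask scores
solidity exactly 1; the mask is always contained in its hull raster, so
solidity ≤ 1 by construction.  The same perimeter/circularity definitions
are reused verbatim by the degeneration-index module.

## Motion tracking (`track`)

Angles follow the image convention (y down): α = atan2(Δy, Δx) ∈
(−180°, 180°], 0° right, +90° down, ±180° left.  Tracks are resampled to
5-min intervals before summarizing (the published convention for manual
tracking); length is the sum of Euclidean steps and velocity =
length / elapsed time.  The per-track mean angle is the *arithmetic* mean
of signed per-step α — matching the reference tracker's per-track
averages, whose published grand means near −60° are only consistent with
signed arithmetic averaging — with a circular-mean variant behind a flag
(`circular_mean=True`) for tracks straddling the ±180° cut.  Turning
classes are 45°-wide sectors centred on 0/±180° (horizontal), ±90°
(vertical) and ±45°/±135° (diagonal); boundary ties go to the
lower-|α| class.

Note one deliberate separation: *recovering* the generator's speed uses
native-interval (30-s) summaries, because 5-min resampling shortens a
randomly-wandering path by the mean resultant length of its heading
distribution (≈ 0.86 at κ = 4) — an intended property of the smoothing,
not an estimator defect.

## Outline PCA (`dyn_pca`)

The outer boundary of each mask is traced at subpixel resolution
(marching squares), smoothed exactly as in the perimeter estimator,
canonicalized — counterclockwise on screen, starting at the boundary point
nearest the image bottom-centre, where the oriented movies anchor the
cone's origin — and resampled to 250 points equally spaced by arc length:
a 500-dimensional shape vector per frame.  Without the canonicalization,
outline correspondence across frames is meaningless.  PCA is computed by
SVD of the column-centred matrix; components are sorted by variance with
the sign fixed so each component's largest-magnitude loading is positive
(runs are bit-reproducible).  Explained variance is reported per component
and cumulatively.

Two scalar dynamics readouts are provided.  `trajectory_length` is the
summed frame-to-frame path in the (PC1, PC2) plane; `trajectory_extent` is
the diagonal of the trajectory's bounding box.  The summed path length
rewards *any* movement, including back-and-forth wander — a weakly
directed cone reverses its shape trajectory constantly and can accumulate
a longer path than a steadily advancing one (about 2× in the default
condition comparison).  The "long directed trajectories" phenotype of
healthy cones is therefore measured by the extent, which separates the
conditions in the expected direction; both numbers are reported.

## Tensor decomposition (`dyn_tensor`)

The movie is a rows × cols × frames tensor of mask intensities.  The
decomposition is the plain truncated HOSVD: factor *n* holds the leading
*r_n* left singular vectors of the mode-*n* unfolding, and the core is the
tensor contracted with the factor transposes.  It is deterministic (sign
convention: largest-|entry| of each factor column positive), matches the
classical tensor-toolbox construction, and at movie scale the optimality
gain of iterated alternatives is negligible — higher-order orthogonal
iteration (HOOI) is available behind a flag.  For the very wide unfoldings
a movie produces, the factor basis is computed from the eigendecomposition
of the small Gram matrix M·Mᵀ rather than a direct SVD (same basis, much
cheaper).

Default ranks are (20, 20, 2): two temporal components mirror the two
principal movement patterns of interest.  Note a moving cone is *not*
low-rank — at study scale the relative reconstruction error at these ranks
is ≈ 0.5 — the decomposition is used for pattern extraction, not
compression.  The pattern image of temporal component *k* is
*P_k* = *U*₁ *G*[:,:,k] *U*₂ᵀ (the core contracted to temporal column *k*);
its construction in the original work is not fully specified, so this
definition is a documented choice.  Pattern images are min-max rescaled to
[0, 1] only on export.  `dominant_orientation` summarizes a pattern image
by eigen-analysis of its image-summed structure tensor (0° = horizontal
structures, 90° = vertical); vertically and horizontally moving synthetic
cones yield pattern-2 orientations ≈ 90° apart.  Movies compared within a
study share one canvas; no cross-movie spatial registration is performed
beyond the generator's common bottom-centre anchoring.  Condition-stacked
4-mode tensors are noted but not implemented.

## Degeneration index (`degen`)

DI = fragmented / total area of the axonal network.  Particles are
8-connected components; the published filters (area 20–10000 px²,
circularity 0.5–1.0, exclude edge-touching particles) gate the fragmented
sum; the total is the full foreground count (the RawIntDen of a 0/255 mask
divided by 255).  Fields are sampled as 5–10 disjoint 700 × 700 px
quadrants: size-aligned tile positions are tried first in seeded random
order (guaranteeing dense packings are found), then a finer grid greedily
fills in; operator-marked stacking regions are supplied as an exclusion
mask and avoided entirely.  On synthetic fields the pipeline recovers the
raster ground-truth DI within ±0.001 across true DI ∈ [0, 0.3] when
segmented with the simple (no-background-subtraction) configuration; the
full published recipe remains the default for real micrographs, whose
uneven illumination it was designed for.

## Aggregation and statistics (`aggregate`)

Measurements nest as growth cone → animal → genotype×age.  Per-animal
summaries are mean, SEM = sd/√n (undefined for n = 1) and n.  The genotype
"total mean" is the **unweighted** mean of per-animal means — weighting by
per-animal N does not reproduce the published totals — and the genotype
SEM column is likewise the unweighted mean of per-animal SEMs, computed
from unrounded values.  Printed-table rounding is half-away-from-zero, 2
decimals (3 for velocities in µm/s).  Group comparisons: two-sided
Mann–Whitney (exact when sample sizes permit; identical all-tied groups
return p = 1 by convention) and per-metric t-tests with Holm–Šidák
step-down adjustment across the metric family.  p-values from real data
are not reproduction targets — they depend on the original micrographs.

## Study scale and determinism

The two-condition synthetic study (`study.run_batch`) runs 40 movies per
arm at 160 × 160 px, 0.5 µm/px, 4-µm blob radius, 121 frames — chosen so a
full comparison (segmentation, tracking, PCA, HOSVD per movie) completes
in a few minutes on one core while every condition contrast remains
measurable.  All randomness flows from explicit integer seeds through
`numpy` generators; identical seeds give byte-identical movies and
run-to-run identical decompositions.

## Known limitations

- The optical model is binary-plus-noise; no halo, shading, or focus
  drift.  Segmentation robustness claims do not transfer to raw
  phase-contrast data.
- Outline correspondence relies on the bottom-centre anchor; masks whose
  boundary approaches the anchor ambiguously can swap start points between
  frames (a small tangential ripple in the shape vectors).
- The arithmetic mean angle is ill-defined for tracks straddling ±180°;
  the circular variant exists but changes the statistic.
- Published group values for image-derived metrics (areas, Feret, DI of
  real cultures) are not recomputable without the original images; only
  the aggregation arithmetic over printed per-animal values is verified
  exactly.
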