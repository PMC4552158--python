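# Methods

## The segmentation model

Soil CT volumes order their materials by gray value: air-filled pores are
darkest, water and organic matter (roots, debris) intermediate, minerals
brightest.  No global threshold separates roots from everything else, because
partial-volume voxels on mineral–pore interfaces average mineral and air into
exactly the root gray range, and organic debris *is* root-gray material.  The
protocol therefore works by elimination: segment the minerals (an easy,
high-contrast problem), grow them to swallow the mixed-voxel shell, subtract,
then segment roots against air inside the remaining root-and-pore space, and
finally delete every connected structure too small to be a root segment.

Assumptions: isotropic voxels; material brighter than background in both
surface-determination passes (minerals vs air, roots vs air); root segments
large relative to debris (the size filter is the discriminating mechanism);
container walls, if present, bright enough to be captured with the minerals.

## Surface determination

An operator (or the phantom helper) supplies example voxels of background and
material.  The initial threshold is the midpoint of the class means (ISO-50).
The initial mask thresholds the *raw* gray values; a Gaussian-smoothed copy
of the volume (sigma `gradient_smoothing_sigma`, default 1 voxel) is used
only to estimate gradients.

Refinement is anchored at the boundary voxels of the initial mask.  From each
anchor, the gradient-magnitude profile is sampled (linear interpolation, 0.5
voxel steps) along the local gradient direction over ±`search_distance_voxels`
(default 3).  The profile maximum — sub-voxel refined by a three-point
parabola — is the relocated surface position; voxels between the old and new
position are reclassified by which side of the located edge they fall on.
Conflicting reclassifications from different anchors are resolved by majority
vote, ties keeping the initial class.  Three guards matter in practice:

- **Domain cuts are not edges.**  Where a restricting domain truncates the
  mask (step 4 runs only inside the roots-and-pores domain), boundary voxels
  whose only "background" neighbours lie outside the domain are not anchored,
  and profiles are truncated at the domain edge.  Without this, anchors on
  the mineral-facing side of a root chase noise and erode the root surface.
- **No-edge guard.**  Anchors whose best profile peak is below 30% of the
  median peak keep their threshold position; a window that contains no
  credible edge should not move the boundary.
- **Curvature compensation.**  On a curved interface blurred with an
  effective width sigma, the gradient maximum shifts toward the centre of
  curvature by about sigma²·(k1+k2).  The total curvature is estimated as
  the divergence of the unit gradient field at the located peak; sigma² comes
  from a log-domain parabola through the peak (exact for a Gaussian-shaped
  peak), taken as the median over all anchors because the interface width is
  a global property of the imaging blur while per-anchor estimates are noisy.
  Without this term, tubes of radius r lose a sigma²/r shell everywhere —
  several percent of root volume at the radii and blurs typical here.

Accuracy on noise-free phantoms: blurred planar edges are recovered within 1
voxel for threshold biases up to the search distance; a blurred ball of
radius 12 with a threshold biased ~2 voxels outward is recovered within 2%
of its analytic volume.  Bias tolerance degrades as the bias approaches the
search distance (the peak leaves the window), which matches the interactive
practice of setting thresholds within a couple of voxels using a preview.

## Fractional dilation

"Dilate by 0.5–1 voxels" is meaningless for centre-to-centre distances (no
neighbour is closer than 1 voxel).  The mask surface is taken to lie half a
voxel beyond the outermost foreground centres, so a background voxel joins
the dilated ROI when `edt - 0.5 <= radius`, with `edt` the Euclidean distance
to the nearest foreground centre.  Radius 0 is the identity; radius 0.5 adds
exactly the face neighbours (the one-voxel mixed shell's core); radius 1 adds
the edge neighbours; integer radii coincide with classical dilation by a ball
of radius r+0.5 sampled at voxel centres.

## Component size filter

Connected-component labeling defaults to 26-connectivity (thin roots connect
diagonally; 6-connectivity fragments them), and deletion is strict:
"smaller than `min_voxels`" is deleted, equality survives.  The default of
10,000 voxels is resolution-dependent and deliberately not auto-scaled; it is
exposed as a parameter (tests on 96-cube phantoms scale it down with the
phantom, e.g. 2,000).

## Local thickness

Root diameter is the Hildebrand–Rüegsegger local thickness: the diameter of
the largest sphere fully inscribed in the mask that reaches the voxel.  The
inscribed radius at a centre is `edt - 0.5` (an isolated voxel has diameter
1).  A sphere reaches a voxel when any part of the voxel's unit cube does —
centre distance within `radius + 0.5` — because with centre-only containment
the sphere defining a tube's diameter would never touch the tube's own
surface voxels.  Spheres are painted in descending radius order with radii
quantised to 0.5-voxel steps (bounds the quantisation error at one voxel of
diameter while keeping the pass count linear in the maximum radius); a
brute-force inscribed-sphere search is the test oracle.

The diameter distribution is a histogram over *surface elements* — boundary
voxels of the mask — with a default bin width of one voxel in mm.  The
fine-root fraction sums frequencies strictly below the cutoff (default
0.25 mm), apportioning a straddling bin linearly.  Counts are voxel counts;
area weighting of surface elements is not attempted.

## Region-growing baseline

Flood fill at 26-connectivity from seed voxels, accepting voxels within a
gray tolerance of a reference: the mean seed gray (fixed mode) or the running
mean of all accepted voxels, updated after each accepted shell (adaptive
mode — the update rule is this package's concrete choice).  Growth can be
confined to a search box, and results accumulate across calls to model the
stepwise interactive workflow.  On phantoms, a tolerance wide enough to cover
a root well also leaks through the partial-volume shells of the soil matrix,
while a safe tolerance under-covers — the dilemma that motivates the
protocol; and growth can never reach a root not voxel-connected to a seed.

## The phantom generator

Phantoms emulate the specific obstacles of undisturbed field cores: roots as
random-walk tubes (downward drift, gentle taper, optional branching),
rasterised with 3× supersampling (a voxel is root when at least half of its
27 sub-samples fall inside the tube); mineral aggregates as overlapping
random ellipsoids grown to a target fill fraction (default 0.5); organic
debris as small root-gray blobs kept below the size filter by default;
per-voxel Gaussian class noise; a Gaussian blur (default sigma 1 voxel) that
creates the mixed-voxel shell; optional linear pore-gray drift (moisture) and
container wall.  Default gray means (air 5000, water 12000, root 18000,
mineral 45000, wall 43000 on the 16-bit scale; sd 1500) respect the field's
ordering, with the wall deliberately mineral-like.  Truth masks come from
the pre-noise rasterisation and are exact by construction; identical seeds
give bit-identical phantoms.

What the generator does *not* emulate, so passing tests do not speak to it:
direct root–mineral contact (a thin air film — a rhizosphere gap — always
separates roots from aggregates and debris, whereas real contact zones mix
root and mineral gray); reconstruction artifacts (beam hardening, rings,
streaks); water-filled pores as a distinct phase; roots touching debris.
Unconnected roots are kept at least 3 voxels apart; in small volumes two
roots passing close can still be bridged by mixed-voxel false positives and
merge into one component — at the 256-cube reference geometry this does not
occur.

## Problem sizes and validation design

The test suite and the acceptance script validate on: a 256-cube reference
phantom (three roots, mineral fill 0.5, blur 1) for overlap/component/volume
recovery; ten 192-cube phantoms with 1–10 roots for the volume-recovery
regression (recovered vs true volume, OLS); 96-cube phantoms for the
mixed-voxel contrast (false positives within 2 voxels of mineral surfaces,
dilation 0 vs 1) and the unconnectedness contrast (region growing tolerance
1200 — the widest leak-free setting on that phantom — vs the protocol); and
analytic solids (balls r=4–12, cylinders r=3–8) for surface determination
and thickness.  Oracles are independent routes: brute-force flood fill for
components, exhaustive neighbour enumeration for boundaries, direct distance
evaluation for fractional dilation, exhaustive inscribed-sphere search for
thickness, analytic volumes for geometry.

## Numerical choices and degenerate inputs

- Float volumes are downscaled to 16-bit by a quantile-clipped linear map
  (default 0.05% per tail) guarding against reconstruction outliers; a
  constant volume is a degenerate-volume error, not a silent all-zero.
- 8-bit input is promoted by left-shift scaling; slice directories are read
  in lexicographic order and must agree in shape.
- The whole-volume ROI of step 3 excludes a 1-voxel frame (boundary voxels
  lack full neighbourhoods for gradient estimation).
- Anchors with numerically zero gradient keep their class; gradient-peak ties
  resolve toward the current boundary position.
- Masks are written as 8-bit TIFF (255 = foreground), volumes as 16-bit, each
  with a JSON sidecar carrying the voxel size; round trips are bit-exact.
- Empty masks: thickness and evaluation against an empty truth raise; mask
  comparison of two empty masks warns and defines Dice as 1.

## Known limitations

- Anisotropic voxels are not supported.
- Thickness under-measures structures thinner than ~3 voxels (quantisation
  plus voxel-centred spheres); at the paper-scale resolutions this affects
  only the finest roots, which land in the lowest histogram bins regardless.
- The surface determination assumes a two-class contrast within its domain;
  a third material with intermediate gray inside one domain (e.g. dense
  water-filled pores against roots) degrades the example-midpoint threshold.
- Throughput/interactive-time claims of the original workflow are not
  reproducible in software and are out of scope; the JSON run logs are the
  reproducibility counterpart of a standardized, operator-minimal protocol.
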