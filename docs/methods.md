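# Methods

This note documents the models, conventions and numerical choices behind
`digispec`, and what the synthetic validation does and does not show.

## Coordinate and label conventions

World units are millimetres. Voxel indices are 0-based; the center of
voxel `(i, j, k)` is `origin + index · spacing`; all voxel distances are
center-to-center. One grid carries all labels (0 background, 1 specimen,
2 tumor, 3 mucosa); tumor and mucosa override specimen, and the
*specimen support* is the union of labels {1, 2, 3}. Axes follow the
specimen: +y anterior–posterior (sections are x–z planes), +z "up"
(the mucosal cap), +x the craniomedial side. The unit of discretization
tolerance used throughout the tests is one voxel space diagonal
`d = ||spacing||`.

## Surface extraction

The outer contour is the iso-0.5 surface of the support indicator,
triangulated by marching cubes after Gaussian smoothing with σ = 1 voxel
(`smoothing="off"` meshes the raw indicator). Smoothing is the default
because the staircase normals of a binary isosurface inflate surface
area by ~9% on digitized spheres, while the smoothed surface reproduces
analytic sphere area and volume to < 0.5% with sub-voxel vertex error;
watertightness is preserved either way. Degenerate faces are disallowed
at extraction. Mucosa vertex flags are set where a vertex lies within
one voxel diagonal of a mucosa voxel center.

## Distance fields and margins

Tumor distances use the exact Euclidean distance transform with
anisotropic sampling (distance to the nearest tumor *voxel center*, not
to a meshed tumor surface — simpler, and consistent with a mesh-based
definition within about one voxel at the default 0.3 mm spacing). The
margin map samples this field trilinearly at each non-mucosa surface
vertex. Per-region margin is the minimum over the region's included
vertices — the minimal-margin convention of pathology reports — and the
adequacy rule is strict: inadequate iff margin < 5.0 mm, adequate at
exactly 5.0. A region whose vertices are all excluded (entirely mucosal)
is reported `not_assessable`, never silently adequate.

A knife-edge case worth knowing about: when the true margin equals the
threshold exactly (concentric spheres R = 15, r = 10 mm), the measured
minimum falls a fraction of a voxel *below* 5.0 (≈ 4.95 mm at 0.3 mm
voxels) because the minimum statistic picks the negative tail of the
±h/2 lattice noise, and the strict rule then calls every region
inadequate. This is a property of any unbiased discrete estimator at a
boundary-exact margin, not of this implementation; margins even one
voxel diagonal away from the threshold classify robustly.

## Five-region partition

The deep direction is the normal of a total-least-squares plane through
the mucosa-flagged vertices, oriented toward the specimen interior. The
deep-central region is a cone with apex at the tumor-support centroid
(an `apex_override` mirrors manual placement) and half-angle 45°,
membership tie-broken *into* the cone. Remaining vertices are classified
by azimuth about the cone axis measured from the anterior direction (the
projection of posterior→anterior onto the cone-base plane): [−45°, 45°)
anterior, [135°, 225°) posterior, and the two side quadrants
craniomedial/caudolateral disambiguated by the projection of a hint
vector; half-open intervals make boundary azimuths deterministic. The
45° half-angle matches the 2D sectioning rule (two 45° lines from a
mucosa-parallel line subtend a 90° deep wedge) and is configurable.

A geometric consequence of the minimum statistic: a quadrant's minimum
margin is often attained just outside the cone boundary, where the
surface approaches the tumor obliquely. Quadrant margins are therefore
systematically closer to the deep margin than an "equatorial" intuition
suggests; deep-flagging phantoms used in tests pair a tall, narrow tumor
with a wide specimen so the deep call flips alone.

## Conventional slice-based emulation

Blocks are coronal, of equal nominal thickness `L/n` with
`n = ceil(L / mean_thickness)`. Anterior/posterior margins are
(tumor-free block count at that end) × (L/n) — a step function of tumor
extent with step = mean thickness, which is exactly the quantization
that makes slice counting unreliable when actual spacing varies. Sector
margins are read on each tumor-bearing block's central cross-section:
contour pixels (mucosa excluded) are classified against two 45° lines
through the tumor centroid, oriented by the principal direction of that
section's mucosa pixels (falling back to a global deep hint when a
section shows no mucosa), and distances aggregate across sections by
minimum — consistent with minimal-margin reporting; the aggregation rule
is a package decision, as published descriptions leave it open.

## Synthetic phantoms

Phantoms are smoothed ellipsoids (optional radial bump noise from a
Gaussian-filtered field on the direction sphere) that must fit the 59 mm
scanner-container bore; tumors are interior ellipsoids on the reported
depth-of-invasion scale (defaults ~4–6 mm semi-axes, randomized 2.5 mm
up to ~0.4 of the specimen's smallest axis); default spacing is 0.3 mm
isotropic, matching the 3D acquisition. Mucosa is the surface cap whose
outward normal (from the smoothed-indicator gradient) lies within 60°
(configurable) of +z. Ground truth margins are computed by dense brute
force — nearest tumor voxel from every non-mucosa boundary voxel center,
classified by an independent scalar implementation of the region rules
using the phantom's exact axes — so they can arbitrate the pipeline.

Observer outlines threshold the tumor's signed distance at
`bias + noise`, with noise a Gaussian-filtered field (correlation length
5 mm) scaled to `roughness_mm` standard deviation: positive bias dilates
smoothly, as a human over-contouring would. Erosions that annihilate the
tumor raise an error naming the smallest surviving bias. Default
observer biases (+1.5 and +1.0 mm, roughness 0.8 mm) encode the reported
asymmetry — overestimation far exceeding underestimation — and produce
O95HD values of roughly 1–3 mm per case, inside the reported 0.9–11.8 mm
overestimation range.

Sectioning cuts coronal blocks at jittered thicknesses (uniform
`mean ± jitter`; jitter must stay below the mean or section order would
be ambiguous), takes each block's support-bearing central slice, warps
healthy tissue toward the tumor so tumor-to-edge distances contract by
`shrink_healthy` while tumor pixels stay put (distance-proportional
radial displacement, blended smoothly at the tumor boundary), optionally
tears a random wedge of healthy tissue from one section, and places each
section on its slide with a random rotation/translation. Corresponding
anatomical points (specimen-boundary pixels at spread azimuths) are
recorded in both frames, and the true placement transforms and true
center positions are kept as ground truth.

What the phantoms do *not* emulate: real anatomy (no tongue shape, no
muscle texture), imaging contrast or noise (labels only), non-rigid
fixation deformation beyond the radial shrink model, and container
compression. Passing tests therefore demonstrate the correctness of the
geometry, statistics and reconstruction machinery under known truth —
not clinical performance on real specimens.

## Registration and stacking

Section-to-reference registration is a least-squares similarity fit
(Umeyama; rotation + isotropic scale + translation, reflection excluded)
on ordered landmark pairs; the isotropic scale partially compensates
uniform shrinkage. Stacking resamples each registered section
(nearest-neighbour — labels are categorical) into a common in-plane
frame and replicates it across its slab (nearest section center along
y): a single stained section stands in for its whole block, exactly as
in conventional practice. The stacked volume's extent runs half a
section thickness beyond the end centers, so widening one gap widens the
stack by the same amount. With noiseless landmarks the fit recovers the
placement to ~1e-12, and the end-to-end reconstruction error of the
tumor (95HD vs. the phantom) stays below one mean section thickness —
the resolution limit of the slab model.

## Agreement statistics

95HD surfaces are boundary voxel-face center point sets (exact
brute-force oracles exist at small scale); the percentile Hausdorff is
the max of the two directed p-th-percentile nearest distances (linear
interpolation percentile). Because the Boolean intersection is a subset
of each operand, each directed distance from the intersection surface is
near zero where the outlines agree, making the max-of-directed form the
informative one; percentile and direction mode are arguments. A disjoint
pair yields flagged not-defined distances rather than an arbitrary large
number, so reports can distinguish "no overlap" from "huge error".

Confidence intervals are exact binomial (Clopper–Pearson via the beta
inversion); ratios with zero denominator are not-defined, never 0.
Printed-percent rounding is two-stage half-up (value → one decimal →
integer), matching how statistical software reports are transcribed;
this is the convention under which the reconstruction utility inverts
published tables. `reconstruct_confusion_matrices` enumerates all
O(n³) integer matrices — at n = 45 this is instant and, for both
histology-referenced observer columns, yields exactly one matrix.

## Study orchestration

`run_study` draws per-case substreams from
`SeedSequence(seed, case_index)`, so cohorts are reproducible
byte-for-byte (JSON serialisation rounds floats to 6 decimals). Each
case: random phantom → ground-truth partition and margins → histology
route (sectioning, landmark registration, stacking at true spacings,
resampling onto the imaging grid, clipped to the specimen support since
the outer contour comes from imaging) → observer outlines → margin
reports and 95HD comparisons → cohort confusion matrices against both
the conventional emulation and the histology 3D model. A failing case is
logged and reported, not fatal. Not-assessable slots are dropped from
accuracy pairing with a warning.

## Problem sizes

Defaults target the realistic 0.3 mm voxel scale; the test suite and the
acceptance script run the same code at coarser, faster scales chosen as
adequate for their purpose: 0.8–1.2 mm phantoms for pipeline and cohort
checks (a 9-case cohort takes ~1 s at 1.2 mm), 2.0 mm ≤ 25³ grids for
exhaustive brute-force oracles, and 0.3 mm for the analytic concentric
phantom where sub-voxel margin accuracy is the point. All tolerances on
geometric checks are expressed in voxel diagonals of the grid under
test, so they scale with the chosen spacing.

## Known limitations

* Margins are measured to the tumor voxel support; at coarse spacing
  this overestimates distances to the continuum tumor by up to ~h/2.
* The conventional emulation reads one section per block; very thin
  tumor protrusions between sections are invisible to it (by design —
  that is the sampling error being studied).
* The mucosa plane fit assumes the cap is roughly planar; strongly
  curved or fragmented mucosa would need a local parameterisation.
* Landmark correspondence is exact in simulation; human landmark error
  can be emulated only by adding noise to the landmark lists.
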