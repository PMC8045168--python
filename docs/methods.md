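# Methods

## The planning model

The package plans two parallel fixation screws through the distal acromion
on a watertight triangulated bone surface, in millimetres, right side
(left-side inputs must be mirrored by the user before loading). The bone is
treated as a *solid*: the segmentation that produces the surface (threshold
plus region growing) fills the trabecular interior, so a ray's in-bone
intervals are the segments between successive surface crossings. A
hollow-shell mesh must be voxel-filled (`mesh_from_volume`) before
planning.

### Safe corridor as ray classification

The rendering trick the procedure emulates — turning the bone
semi-transparent and looking down the acromion's axis until a bright oval
appears — is operationalized as parallel-ray classification. For a viewing
direction `d`, a pixel grid (default 0.25 mm, planner runs use 0.5 mm) is
laid on the plane orthogonal to `d` and each pixel's ray is intersected
with the mesh. A pixel is **safe** when

* the ray crosses the solid exactly once (one continuous in-bone segment;
  two or more segments mean the path exits and re-enters the cortex — a
  breach), and
* its chord reaches the corridor-grade floor (below).

Intersection is computed by rasterization: all triangles are projected to
the pixel grid in one vectorized pass and the plane of each triangle is
solved for the ray parameter at each covered pixel. Watertightness makes
crossings pair into intervals; the pairing is validated per pixel (even
count, alternating enter/exit orientation, no coincident hits). Grazing
configurations — hits within 1e-6 of a triangle boundary, odd parity,
coincident hits, or pixels under edge-on triangles — are re-cast with four
deterministic sub-pixel offsets (≤ spacing/100); pixels still ambiguous are
conservatively marked unsafe. The whole grid additionally carries an
irrational sub-pixel anchor offset so axis-aligned synthetic geometry does
not place mesh edges exactly on pixel centers.

### The chord floor: why "safe" requires near-full-length chords

A fixed absolute floor (the configurable `min_chord`, default 10 mm) is not
sufficient to define the corridor: tilting the view of any convex rod
*grows* the silhouette while chords stay above a small floor, so raw safe
area would be maximized by oblique, clinically meaningless views, and short
paths through the thick proximal bone (which never cross the fracture)
would count as corridor. Both the direction objective and the final
corridor map therefore raise the floor to **0.9 × the 95th-percentile
chord** — the corridor consists of rays that run essentially the full
length of the bone. For the objective the reference chord is the maximum
95th-percentile chord over the whole search cone, so all candidate
directions are scored against the same full-length standard; this makes
the extrusion axis the provable optimum for straight rods (verified to
within 0.1° in the tests). The 0.9 ratio leaves room for the genuine
mediolateral chord spread that bone curvature produces (about 10% between
the convex and concave edges of a 30° arc) while excluding proximal-only
paths; it is exposed as `rel_chord`.

### Direction search

Search is restricted to a cone (default half-angle 30°, planner cohort runs
15°) around the anatomical axial-view axis — supplied by landmarks,
generator metadata, or defaulting to the mesh's longest principal axis —
because the clinically valid view is anatomically constrained. Coarse
quasi-uniform spherical grid at 3°, then a shrinking 3×3 tangent-plane hill
climb to 0.5° (cohort runs 1°). The search runs on a coarser grid (0.5–0.8
mm) than the returned map; everything is deterministic, ties resolved by
grid order.

### Zone extraction, entry coherence, splitting

The largest 8-connected safe component is traced to a sub-pixel polygon
(marching-squares contour at the 0.5 level). Corridor rays must also enter
through the common anterior face: the entry depth `t_in` over the safe
pixels is fitted with an iteratively reweighted plane and pixels deviating
by more than `entry_tol` (default 2 mm) are dropped. This removes rays that
only achieve their chord by slipping in through the sloping inferior cortex
behind the tip (their entries leave the face plane by several mm), while an
oblique but planar entry face passes untouched — extruded test shapes are
unaffected.

The zone is divided by the line perpendicular to its major principal axis
(area moments via Green's theorem) at the offset that exactly bisects the
area (Brent's method); for symmetric zones this is the centroid line. The
medial half is identified by projecting the half centroids on the direction
toward the AC-facet landmark.

### Maximal screws

Per half: maximum inscribed circle by Euclidean distance transform on a
0.1 mm raster (first maximum in scan order on ties) polished by Nelder-Mead
against the exact polygon boundary — accurate to 0.05 mm against a 0.01 mm
brute-force oracle. The screw axis is the pixel ray at the circle center;
entry is its anterior cortex crossing and the length the full bicortical
chord (flush exit, no protrusion allowance). Containment of the cylinder is
verified with 96 surface-parallel rays: each must hold one in-bone interval
covering the axis chord, with an allowance of two screw radii at the two
cortical crossings (cortex obliquity up to ~63°; an oblique entry always
leaves part of the screw circumference proud of the surface) and 0.05 mm
elsewhere. On failure the radius shrinks in 0.05 mm steps (max 10); if the
inscribed center sits against a slanted-cortex edge where shrinking cannot
help, the fit retries from the inscribed circle of the eroded half
(0.3/0.6/1.0 mm), which recenters inward. Inter-screw clearance defaults to
0 — the two maximal screws may touch, as their inscribed circles both touch
the split line by construction — with a positive clearance available that
shrinks both radii proportionally.

### Measurements

* **L1–L4**: straight-line 3D distances from the screw entry points to the
  AC-facet landmark point and the distal anterior edge (caliper-style;
  a point-to-facet-patch alternative is available via `facet_mode`).
* **Plane A**: total-least-squares plane of the superior patch vertices,
  normal oriented along the mean outward vertex normal. **α** (downdip) =
  90° − angle(screw, normal), in [0°, 90°].
* **Plane B**: perpendicular to plane A through the zone centroid. Its free
  rotation is fixed by a reference axis. With the corridor direction itself
  as reference (the naive choice) β vanishes identically, because the screw
  direction always lies in the plane spanned by plane A's normal and its
  own in-plane projection. The pipeline therefore uses the *anatomical
  axial-view axis* as the reference, making **β** the mediolateral
  inclination of the planned screws relative to the anatomical axial plane
  — a quantity that is genuinely nonzero and has the few-degree scatter
  reported for this measurement.
* Both screws share the corridor direction, so each subject has a single
  (α, β) pair.

All measurements are rigid-motion invariant (tested to 1e-6).

### Statistics

Group summaries are mean and SD (n−1). Combined rows use the exact total
sum-of-squares decomposition, so combining two group summaries reproduces
the full-sample mean/SD to machine precision — and the combined rows of a
printed summary table can be recomputed without raw data. The default test
is the pooled (Student) two-sample t with df = n₁+n₂−2, which is what the
published screw length/diameter t values reproduce from their printed
summaries (within 1%, the rounding of 2-decimal inputs); Welch is
available. p values are two-sided (scipy's t distribution); the table
formatter prints them to 3 decimals with the sub-0.0005 "0.000" convention,
full precision is kept internally. No multiple-testing correction is
applied. Zero pooled variance yields t = 0 for equal means and ±∞
otherwise.

## The synthetic anatomy

`generate_acromion` sweeps elliptical cross-sections along a plan-view
circular arc: mediolateral semi-axis `a(s)` widening by `taper` toward the
proximal end, near-constant vertical semi-axis, and the section-center line
dipping *linearly* below a level superior crest at `alpha_tilt` — the canal
of a straight screw corridor genuinely makes the downdip angle with plane
A. The crest is formed by clipping the section tops at a constant height
(depth `flat_frac × b`, floored so the strip always spans ≥ 5 ring rows);
ring stations are densified near the tip where the strip lives. The two end
faces are slanted by a smooth chamfer about the canal center: square-
cornered caps would admit corner-to-corner diagonal paths longer than the
canal itself and bias the direction optimizer (an earlier design that
expressed the dip as an ever-deepening wedge failed exactly this way and
was replaced). The arc bends laterally, so the medial screw is the longer
one, as observed clinically. Surface noise is smooth low-frequency radial
bumping (sinusoidal in section angle and arc length), not white noise, to
keep the swept solid watertight. Landmarks (AC facet on the medial rim 6 mm
from the tip, anterior edge at the top of the distal face, superior crest
vertex patch) and a ground-truth record (canal chord, realized downdip,
axial-view hint with its built-in observer error, section dimensions) are
emitted with each subject.

Cohort defaults (all truncated at 3 SD plus hard validity bounds): canal
minor semi-axis N(2.9, 0.4) mm male / N(2.0, 0.3) female; centerline length
N(51, 4) / N(42, 4) mm; mediolateral semi-axis N(9.5, 0.9) / N(8.0, 0.8);
arc angle N(30°, 8°); downdip N(14°, 5°); axial-view hint error N(0°, 4°)
per axis. These are constructed so that pipeline outputs land near the
magnitudes of published two-screw morphometry (male medial screw ≈ 51 mm ×
5.7 mm, female ≈ 42 mm × 3.7 mm, α ≈ 14°); they are synthetic definitions,
not patient data. What the generator does **not** emulate: cortical/
trabecular density contrast, the hooked/curved acromial shape classes,
fracture lines, osteophytes, and segmentation noise beyond smooth bumps —
passing tests demonstrate correct geometry processing and statistical
behaviour, not clinical validity on real scapulae.

## Numerical choices and problem sizes

* Pixel spacing: 0.25 mm for single-subject precision work, 0.5 mm in
  cohort pipelines (screw lengths change < 0.2 mm between the two).
* Inscribed-circle accuracy 0.05 mm; area-bisection tolerance 1e-6 mm.
* The voxel ray-marching cross-check uses 0.2 mm voxels with trilinear
  occupancy thresholded at 0.9 (the threshold compensates the half-voxel
  dilation of surface voxelization; calibrated once against the analytic
  elliptic rod, where it classifies > 99.5% of pixels correctly. The
  package's own classifier matches the closed form exactly there).
  Agreement with the package classifier is asserted at ≥ 99% over pixels
  where the oracle's own classification is locally stable; along sub-voxel
  discretization boundaries — widest where the concave surface runs
  tangent to the rays — two discrete classifiers legitimately differ.
* Cohort runs in the test suite and the acceptance script use 16 + 16
  subjects: the built-in sex effects are ≈ 3 SD, so detection power at
  p < 0.001 is essentially 1 already at that size. The null calibration
  (100 seeded cohorts with identical sex distributions, each variable
  non-significant in ≥ 90%) runs at the measurement level through
  `build_tables`.
* Subject failures in a cohort are logged and excluded; the batch driver
  aborts if more than 20% fail. Across 80 default-cohort subjects the
  current pipeline plans all 80.

## Known limitations

* The corridor model treats bone as homogeneous solid; screw purchase,
  thread engagement and density-weighted trajectory quality are out of
  scope.
* Screws are parallel to the corridor direction; independent per-screw
  angulation is not modelled.
* β depends on the chosen plane-B reference axis (see above); with
  landmark-derived axes its absolute scale reflects how that axis is
  defined.
* Landmarks are inputs (or generator outputs); automatic landmark detection
  on real scapulae is not provided.
* Real CT cohorts are not included; all quantitative cohort results are
  properties of the synthetic population.
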