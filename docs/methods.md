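# Methods

This note documents the models, numerical choices, and limitations behind
`chondrometry`. All lengths are millimetres; no unit metadata is trusted
from input files.

## Measurement model

Cartilage thickness at a point `p` of the articular (cartilage) surface is
defined as the closest-point distance

t(p) = min over the bone surface S of ‖p − s‖,

where the bone (cartilage-free) surface has been rigidly registered into the
cartilage scan's frame. The direction of the query is fixed: cartilage
vertex → bone surface. This matches how subregions are defined (on the
cartilage surface) and avoids the ray-casting ambiguities of normal-based
thickness definitions; a surface-normal variant is deliberately not
provided. Distances above a validity ceiling (`max_valid`, default 10 mm)
are flagged invalid and excluded from statistics — they indicate points over
cartilage-free bone or registration failure, not cartilage.

Per-subregion statistics are the arithmetic mean and the sample standard
deviation (n−1) over valid points. Study-style reports round to 0.1 mm
(half away from zero). The study-level summary takes column means over
specimens per (condyle, flexion) cell, and the overall mean as the mean of
the four column means — not the grand mean of cells — so unbalanced columns
do not reweight the summary.

### Precision propagation

Each scan contributes an independent random surface error of SD σ, so the
thickness difference carries σ_t = √(σ² + σ²) = √2·σ. `propagate_precision`
implements exactly this; the invariant σ_t/σ = √2 is enforced at the type
level. For metrology-grade laser scanners (σ ≈ 0.087 mm) this gives
σ_t ≈ 0.123 mm, roughly 6% of a 2 mm cartilage layer.

## Geometry primitives

**Nearest point on a surface.** The point-to-mesh distance is exact
point-to-*triangle* (faces, edges, vertices), computed by Voronoi-region
classification of the query against each candidate triangle, vectorized
over triangles. Candidates are pruned with two KD-trees: the distance to
the nearest vertex gives an upper bound `d_up`, and any triangle containing
a closer point must have its centroid within `d_up + pad`, where `pad` is
the largest centroid-to-corner distance in the mesh. The bound is exact, so
pruned queries agree with a full per-triangle scan to machine precision
(asserted against an independently coded feature-enumeration oracle in the
tests).

**Deviation metrics.** RMSD and AD between two models are computed
asymmetrically — vertices of the first mesh against the surface of the
second — which matches inspection-software convention and keeps the metric
well defined; a `symmetric` flag averages both directions. AD is unsigned
by default; `signed=True` signs each distance by the side of the footpoint
triangle's outward normal. The repeatability design (n repeated models →
n(n−1)/2 pairwise metrics and their means) is exposed as
`pairwise_repeatability`.

**Sphere fitting.** Marker spheres are fit by geometric least squares:
minimize Σ(‖p−c‖ − r)², Gauss-Newton from a Coope-style algebraic
initialization, step tolerance 1e-10 mm, at most 100 iterations. The
geometric objective is the right one for partial-coverage marker scans,
where algebraic fits are biased. With a caller-fixed radius, three points
suffice; the center is then initialized by lifting the circumcenter of the
first three points off their plane (the centroid is a stationary point by
symmetry and cannot seed the iteration; of the two mirror solutions the one
on the +normal side of the vertex order is taken, deterministically).

**Rigid registration.** Kabsch/SVD on centered corresponding centers, with
determinant correction so a reflection is never returned. The FRE (RMS
residual over corresponding centers after alignment) is reported with every
registration; above 0.2 mm — about twice single-scan precision — a quality
warning is raised. Marker correspondence uses labels when both scans share
them; otherwise all assignments of the inter-center distance matrices are
searched exhaustively (markers number 6–8, so this is trivial) and a
near-tie within 0.05 mm residual raises an ambiguity error rather than
guessing — rotationally symmetric marker layouts genuinely cannot be
disambiguated from geometry.

## Anatomical frame

The standard planes are operationalized as:

* **ML axis** — the line through the centers of spheres least-squares fit
  to the two posterior condylar patches. The standard sagittal plane is
  normal to it. A cylinder fit to the combined posterior facets would be an
  alternative operationalization; the sphere-center construction was chosen
  because it reuses the marker-fitting machinery and degrades gracefully on
  small patches.
* **PD axis** — the medial tibial plateau plane normal (total least
  squares), orthogonalized against ML and oriented toward the condyles
  (proximal). The standard axial plane is normal to the sagittal plane and
  parallel to the plateau.
* **AP axis** — PD × ML (right-handed by construction), with (ML, AP)
  jointly negated if AP points away from the trochlea-side hint patch, so
  AP is always posterior→anterior. For a right knee ML then runs
  medial→lateral; the joint negation is exactly the left-knee mirroring.

The origin is the midpoint of the condylar sphere centers. Landmark patches
(posterior condyles, medial plateau, trochlea) are *inputs* — supplied by
the user or the phantom generator — because no automatic detector is part
of this package. Quality gates: condylar sphere-fit RMS residual above
1.0 mm, or a plateau normal within 10° of the ML axis, abort frame
construction.

## Condylar subregions

With the cartilage mesh in the anatomical frame (x = ML, y = AP anterior+,
z = PD proximal+):

* The cartilage **extent** records the trochlear lowest point (minimum PD
  within the trochlear patch), the per-condyle most posterior points
  (minimum AP), and the total ML width W (max x − min x). The
  medial/lateral split defaults to the trochlear lowest point's ML
  coordinate (configurable). The weight-bearing length per condyle is
  L = 0.6 × (AP of the trochlear line − AP of the most posterior point),
  taken as a straight-line AP distance, not arc length.
* **0° subregion**: the weight-bearing strip y ∈ [y_t − L, y_t], its
  central third in AP, then ML trimmed to ±(0.15·W)/2 about the retained
  set's ML centroid.
* **90° subregion**: a PD band of length L/3 centered at the most posterior
  point, restricted to the posterior aspect (AP below the condylar sphere
  centers' AP; in the frame this is the origin's AP, 0), then the same ML
  trim.

All selections are closed-interval predicates over vertices; ties at
extrema resolve to the lowest vertex index for determinism. The 60% / ⅓ /
15% constants live in `SubregionSpec` and can be overridden. Note that
widening the AP band moves the centroid that anchors the ML window, so
superset monotonicity is guaranteed per rule, not across interacting rules.

## Phantom generator

The bicondylar phantom emulates the distal femur as two spherical condyle
patches (radius 22 mm, centers ±22 mm on the ML axis; sagittal angle
−60°…110°, ML tilt ±40°) plus a partial-cylinder trochlear groove (radius
8 mm) whose edges are lifted proximally so the trochlear lowest point is
unique and central. The cartilage surface is the bone surface offset along
the outward normal by a smooth field t(θ) = t0 + a·cos θ (defaults t0 =
2.0 mm, a = 0), validated against the curvature radius so the offset cannot
self-intersect, and capped at 4 mm peak thickness (physiological).
The default angular step is 2°, giving ~0.8 mm edge lengths and ~8 400
vertices per surface — fine enough that chordal error (≈ R·δ²/8 ≈ 0.003 mm)
is negligible against all tolerances, small enough that the full test suite
and the Monte-Carlo runs complete in seconds.

Markers default to 7 spheres of radius 12 mm in a deliberately irregular
layout (unique distance-matrix matching); a symmetric `ring` layout exists
to exercise the ambiguity path and records a warning.

Scan simulation displaces each vertex independently along its outward
normal by N(0, σ²), drawn separately per scan, so each scan's per-vertex
RMS deviation equals σ (default 0.087 mm). This mimics the depth-dominant
error of laser triangulation; isotropic 3D noise would inflate apparent
surface error by tangential components that scanners largely do not
exhibit. Marker clouds are sampled uniformly on each sphere (400 points)
with radial noise. Everything is driven by one integer seed;
identical seeds give bit-identical phantoms.

### What the phantom does and does not show

Passing phantom tests demonstrates that the *pipeline* — registration chain,
frame construction, subregion rules, closest-point thickness — is correct
and that random scan error propagates as modelled. The phantom does not
reproduce real cartilage geometry (no trochlear asymmetry, no osteophytes,
no partial cartilage loss), spatially correlated scanner error, segmentation
error, or marker mounting compliance; specimen-specific thickness values
are not desk-reproducible and are covered only through the
summary-statistics operations on their published table.

A Monte-Carlo detail worth knowing: the empirical per-point thickness-error
SD on the noisy phantom comes out a few percent *below* √2·σ (≈ 0.107 vs
0.123 mm at the default resolution). The closest-point distance to a noisy
piecewise-linear surface slightly smooths (barycentric interpolation) and
slightly minimizes (picks the nearest bump of) the bone-side noise, which
also produces a small negative bias (≈ −0.03 mm at σ = 0.087 mm). Both are
properties of closest-point measurement on discretized noisy surfaces, not
implementation error; the empirical SD stays within the 15% band around
√2·σ that the error-model check uses.

## Numerical conventions

* Transforms are rotation-first (x' = R·x + t); serialization is a 4×4
  homogeneous matrix, row-major JSON. Reflections are rejected at
  construction (det(R) = +1 within 1e-9). Rotation magnitudes use
  atan2(‖skew‖/2, (tr−1)/2), accurate near zero where arccos loses
  half the significant digits.
* Mesh loading merges duplicate vertices and drops degenerate faces;
  units are assumed mm with no rescaling.
* Report rounding (0.1 mm) uses half-away-from-zero, matching how study
  tables are conventionally typeset; Python's banker's rounding would
  differ on exact .x5 values.
* CLI exit codes: 0 success, 2 input error, 3 geometry/coverage error,
  4 numerical failure.

## Known limitations

* No automatic anatomical landmark detection; patches are inputs.
* No ICP/shape-matching registration path: fiducial registration is the
  method, by design, since shape matching between a cartilage-bearing and a
  bone-only model biases the very distances being measured.
* Thickness is unsigned closest-point distance; it cannot distinguish a
  cartilage surface below the bone surface (registration failure) from
  genuine thickness.
* Exhaustive marker matching is limited to 8 markers.
* The study-summary extremes report both cell-level extremes and column
  means; summaries of published tables take printed (already rounded)
  statistics as input, so sub-0.1 mm conventions (e.g. SD with n vs n−1)
  cannot be recovered from them.
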