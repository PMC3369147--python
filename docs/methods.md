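# Methods

`hipcov` measures femoral-head coverage by the acetabulum in 3D from a
femur surface mesh and an acetabular rim curve, computes the six standard
radiographic measures of acetabular morphology from AP-pelvis landmarks,
and provides the statistical layer (group comparison, observer
reliability, 2D-vs-3D association) plus a synthetic hip generator with
analytic ground truth against which the whole chain is validated. This
note records the models, the conventions the implementation had to fix
where the underlying measurement ideas leave freedom, and the known
limitations.

## Coordinate frame and units

All 3D geometry uses a right-hip anatomical frame: **+x lateral, +y
anterior, +z superior**, coordinates in mm. Input meshes and rim curves
must be expressed in this frame (the head superior, the shaft running
inferiorly). Rim point sequences must be ordered **counterclockwise as
seen from the acetabular (covered) side**; this orientation is what tells
the classifier which side of the rim curve is covered, and it remains
well defined for sockets deeper than a hemisphere, where the commonly
suggested rim-centroid witness falls on the *uncovered* side.

## 3D coverage chain

1. **Head sphere.** A sphere is fit to the femoral head by linear
   least squares (algebraic form) followed by geometric
   (orthogonal-distance) refinement, seeded from the superior-most
   vertices and iterated with residual trimming so neck and shaft
   vertices drop out.
2. **Principal curvatures.** Per vertex, neighbors within a radius are
   expressed in the tangent frame of the outward vertex normal and a full
   quadric `h = a u^2 + b uv + c v^2 + d u + e v + f` is fit; principal
   curvatures are the eigenvalues of the shape operator of that graph,
   signed so convex regions are positive. Default radii: 2.0x and 3.5x
   the mean edge length (two fields; see next step). Vertices with fewer
   than ~6 usable neighbors are flagged and filled from their nearest
   fitted neighbors.
3. **Head-neck junction.** On the convex head the minimum principal
   curvature k2 is positive; at the saddle-shaped junction it is
   negative. Marching along 48 azimuthal meridians from the head apex
   (the antipode of the neck direction), the first positive-to-negative
   zero crossing of k2 is linearly interpolated per meridian. Because a
   finite-window curvature estimator drags the apparent crossing toward
   the head by an amount roughly proportional to its window radius, the
   crossing points are computed at two radii and extrapolated linearly to
   zero radius (Richardson extrapolation); this reduces the junction bias
   from ~2-3 mm to well under 1 mm and makes it nearly independent of
   mesh resolution (5k vs 20k vertices agree within ~0.3 mm). A plane is
   fit to the extrapolated ring with one MAD-based outlier trim (which
   absorbs cam-type bumps), and the mesh is cut along it, keeping the
   apex side.
4. **Regions.** Plane 1 passes through the head center, the centroid of
   the narrowest neck cross-section (minimum-area section over a 0.5 mm
   scan perpendicular to the junction normal) and the shaft center
   (section centroid 12 mm above the distal end; the measurement ideas in
   use do not say where along the shaft this point sits, so the height is
   a documented configurable convention). Its normal is oriented
   anteriorly. Plane 2 is perpendicular to it through the head center,
   with normal along the component of (head - neck) orthogonal to plane
   1's normal, oriented medially. The four quadrants are anterolateral
   (AL), anteromedial (AM), posterolateral (PL), posteromedial (PM).
   Faces straddling a plane are split geometrically, so region areas sum
   to the head area to machine precision.
5. **Covered region.** The rim spline (periodic cubic, chord-length
   parameterized) is sampled (default 512) and each sample projected to
   its exact nearest point on the head surface (KD-tree candidates +
   point-triangle distance). Face vertices and the projected curve are
   mapped radially to the unit sphere about the fitted center; a point is
   covered iff the geodesic arc from it to the covered-cap pole (from the
   rim orientation, above) crosses the curve an even number of times.
   Faces with mixed vertices are midpoint-subdivided (depth 2, 16
   sub-faces) and classified by centroid, giving fractional covered
   areas.
6. **Percent coverage.** Covered area is measured as per-face solid angle
   about the fitted center (Van Oosterom-Strackee), times R^2 for mm^2.
   Denominators are the **full spherical references**: 4*pi*R^2 for total
   coverage, pi*R^2 per quadrant (two perpendicular planes through the
   center always quarter a sphere), 2*pi*R^2 for the anterior/posterior
   aggregates. With this normalization a concentric cup of polar
   half-angle theta_c yields total coverage exactly
   100*(1 - cos theta_c)/2 regardless of where the junction cut lands,
   mesh discretization cancels to first order, and the Monte-Carlo
   oracle (below) is directly comparable. The junction-cut mesh supplies
   the covered area only; area below the junction is, by construction of
   the anatomy, never covered.

Numerical defaults: curvature radii 2.0/3.5x mean edge, 48 meridians,
512 rim samples, 0.5 mm neck scan step, subdivision depth 2. Stability
tests in the suite guard each of these.

## Radiographic measures

All six measures are computed relative to an explicit horizontal
reference carried with the landmarks (by convention pointing from the
contralateral to the ipsilateral teardrop, hence lateral-positive for
either hip); the superior direction is the reference rotated a quarter
turn with the handedness set by `side`. Measures are invariant to rigid
in-plane motions and to mirroring.

* **Extrusion index**: uncovered lateral head width / head diameter,
  clamped at 0 when the sourcil overhangs the head edge (the distance is
  physical).
* **LCEA**: angle between the vertical through the head center and the
  ray to the lateral sourcil, lateral positive.
* **Acetabular index / acetabular angle**: elevation of the medial
  sourcil -> lateral sourcil and teardrop -> lateral sourcil segments,
  up-sloping positive.
* **Crossover ratio**: first intersection of the anterior and posterior
  wall polylines, walking the anterior wall from its lateral end (the
  most lateral intersection wins when there are several); distance from
  the lateral rim to that point over the lateral-rim-to-teardrop
  diameter. No intersection -> the crossover sign is negative and the
  ratio is absent.
* **Posterior wall distance**: signed horizontal offset of the posterior
  wall where it crosses the horizontal through the head center, lateral
  positive; with several crossings the most lateral is used (documented
  convention).
* **Obturator index**: ipsilateral/contralateral obturator width, with
  the 0.8-1.2 film-adequacy screen (inclusive at both ends).

## Statistics

Group comparison uses the pooled-variance two-sample t-test (Welch
available behind a flag). Reliability uses **ICC(2,1)** — two-way random
effects, absolute agreement, single measures — computed from the two-way
ANOVA mean squares
`(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)`; the reliability
literature leaves the model choice open, and this is the conservative
standard when readers and reads are crossed with subjects. Agreement is
labelled on the Landis-Koch bands (slight <= 0.20 < fair <= 0.40 <
moderate <= 0.60 < substantial <= 0.80 < almost perfect). Intra-observer
ICCs are computed per reader across reads and inter-observer ICCs per
read across readers. Associations are simple least-squares regressions
of each coverage outcome on each 2D measure, pooled over both groups,
with Pearson r and its t-based two-sided p; reader/read values are
averaged to one value per subject before descriptives and regression.
No multiple-testing correction is applied (reported, not corrected).
t-tests and regressions are delegated to scipy.stats behind the module's
result types; the ICC is implemented directly and cross-checked against
an independent ANOVA route and against pingouin in the tests.

## Synthetic hip generator

The generator stands in for CT-derived femur surfaces and digitized
radiographs; it defines the conditions under which the chain is
validated.

**Femur.** Implicit union of a spherical head, a neck capsule whose axis
passes through the head center, and a vertical shaft capsule, extracted
by marching cubes at a pitch chosen from the analytic area estimate to
hit the requested vertex count. The head-neck joint uses an **exact
toroidal fillet** (default radius 3 mm) tangent to both surfaces, so the
constructed surface has a genuine concave blend whose zero-curvature
ring is analytic: it sits at axial offset `R*sqrt((R+k)^2-(r+k)^2)/(R+k)`,
within ~0.9 mm of the classical sphere-cylinder tangency circle at
`sqrt(R^2-r^2)`. An optional cam bump (smooth union of an offset sphere
at the anterosuperior junction) produces the aspherical heads seen in
retroversion. Defaults: head radius 24 mm, neck radius 14 mm (0.58
ratio), neck-shaft angle 130 deg.

**Cup and rim.** The cup is a sphere concentric with the head (congruent
joint), radius head + 2 mm; the rim lives on the cup sphere. A rigidly
rotated planar rim cannot produce a radiographic crossover sign under
orthographic projection — its projection is a simple closed curve, and
two arcs of a simple closed curve can only meet at their endpoints — so
the rim model carries the morphology that actually creates the sign:

* a first-harmonic polar modulation (anterior wall shallower, 6 deg),
  the normal anatomic asymmetry that separates the projected walls;
* for retroverted cups, a posterosuperior-to-posterior **wall
  deficiency** (Gaussian bump in azimuth, up to 26 deg of polar angle)
  and a smaller anterosuperior prominence, both growing with the amount
  of retroversion — the posterior-deficiency mechanism of the crossover
  sign, which also drives the posterior wall distance negative;
* a **cranial version twist**: `cup_version` is the version of the
  cranial rim segment, reached by an azimuth-weighted rotation about the
  body axis from the socket's base orientation, which itself follows the
  version but never drops below +4 deg of anteversion (markedly
  retroverted acetabula keep a near-neutral inferior rim; this is what
  lets the projected walls keep their normal ordering caudally and cross
  cranially).

After shaping, the base polar angle is recalibrated numerically (secant
iteration on the spherical Green's-theorem area integral of the curve)
so the rim always encloses exactly the cap fraction
`(1 - cos theta_c)/2` of the sphere. Ground-truth total coverage is
therefore the closed form `100*(1 - cos theta_c)/2` whenever the cup
stays clear of the neck (checked; otherwise the Monte-Carlo value is
used), and regional ground truth comes from a seeded **Monte-Carlo
spherical-integration oracle**: uniform directions classified by rim
membership (numeric polar-angle law in the base frame), the analytic
junction ring, and the analytic region planes — an entirely independent
route from the mesh pipeline.

**Radiograph.** Orthographic projection onto the coronal plane after
pelvic tilt (about +x) and rotation (about +z); no point-source
magnification (non-goal). Landmarks are synthetic conventions: the head
circle from the head sphere; lateral/medial sourcil as the projected
rim's support points in the superolateral/superomedial 45-degree
directions; the teardrop as the inferomedial rim extreme, mirrored about
a body midline 95 mm medial to the head for the contralateral copy; the
horizontal reference as the inter-teardrop direction; obturator widths
from mirrored tilted chords (equal at neutral rotation, skewed by pelvic
rotation). The anterior and posterior walls are emitted as *distinct rim
arcs* by rim-frame azimuth (12 to 168 deg on each side of the superior
pole), matching how readers trace two separate structures; splitting one
closed projected curve at its extreme points instead would make an
interior wall crossing geometrically impossible (see above), i.e. the
crossover sign undetectable.

**Cohorts.** Controls: cranial version N(15, 4) (floor +8), cup depth
N(99, 2.5), inclination N(41, 3). Patients: version N(-11, 3) (cap -6),
depth N(90, 2.5), inclination N(46, 3). Head radius N(24, 1.2) for both.
These values are chosen so the synthetic study reproduces the
*direction* of the clinical contrasts (total coverage ~58% vs ~50%,
posterior deficit concentrated posterolaterally, positive vs negative
posterior wall distance, crossover sign in every patient and no
control) — subject-level magnitudes of real cohorts are not targeted.
Reader noise is applied to landmark *coordinates*, not to final
measures, so it propagates consistently into all six measures: a
persistent per-(subject, reader) bias (0.5 mm SD) plus independent
per-read noise (0.6 mm SD), which makes intra-observer agreement exceed
inter-observer agreement as in real repeatability studies. Per-subject
pelvic tilt N(0, 2) deg and rotation N(0, 1.5) deg. Everything is
reproducible from the single cohort seed.

## Validation and problem sizes

The test suite validates the chain end to end at desk scale: the
spherical-cap closed form on 10k-vertex sphere meshes (within ~0.15
points), junction recovery on 5k/20k-vertex femora (within 2 mm of the
tangency plane, < 1 mm across resolutions), per-region agreement with
the 2^20-sample Monte-Carlo oracle on 20 random hips at 12k vertices
(worst region error ~0.6 points against a 1.5-point gate), strict
posterior-coverage monotonicity over a cranial-version sweep, exact
hand-derived radiographic values, statistical closed forms at 1e-10, and
an 18/16 cohort through the full mesh chain plus 100 null cohorts for
the type-I error rate. These sizes keep the suite and the acceptance
script within a few minutes each on one CPU.

## Limitations

* The synthetic pelvis is landmark-level only: no bone outlines, no
  image formation, no perspective magnification or parallax, so measure
  *magnitudes* (e.g. LCEA around 45-55 deg, PWD around +14 mm in
  controls) sit above typical clinical values even though every
  within-cohort contrast has the clinical direction. Passing tests
  demonstrate correctness of the measurement chain and direction of the
  biology, not clinical calibration.
* The congruent spherical joint couples cup depth to every projected
  landmark; real acetabula decouple these (e.g. near-zero PWD with high
  coverage).
* The crossover-ratio magnitude grows with retroversion severity in the
  generator, whereas severe clinical retroversion often shows near-rim
  (near-zero-ratio) crossovers; only presence/absence and tilt trends
  are asserted.
* Curvature-based junction detection assumes a clean concave transition;
  heavily corrupted meshes (holes, spikes) will fail loudly rather than
  degrade silently, as will rim curves whose projection on the head
  self-intersects after cleanup.
* The ICC factorization (intra per reader across reads, inter per read
  across readers) is a documented convention; reliability studies report
  this layout but other factorizations exist.
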