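# hipcov

3D femoral-head coverage and 2D radiographic measures of acetabular
morphology, for researchers studying hip pathomorphologies such as
acetabular retroversion and femoroacetabular impingement.

Acetabular retroversion tilts the socket so that it opens posteriorly:
the anterior wall over-covers the femoral head while the posterior wall
is deficient. Clinically it is diagnosed on AP pelvis radiographs (the
crossover sign and related measures), but plain films cannot quantify
the 3D relationship between the acetabulum and the femoral head. This
package implements both sides of that comparison and the statistics
linking them:

* **`hipcov.coverage3d`** — percent femoral-head coverage from a femur
  surface mesh and an acetabular rim curve: the rim is spline-fit and
  projected to its nearest points on the head; the head–neck junction is
  found automatically as the zero-crossing ring of the minimum principal
  curvature k2 (convex head → saddle-shaped neck) and the head cut along
  the fitted junction plane; two perpendicular planes through the head
  center (head / narrowest-neck / shaft centers) split the head into
  anterolateral, anteromedial, posterolateral and posteromedial regions;
  coverage per region is `100 × covered area / region area`.
* **`hipcov.radiograph2d`** — the six radiographic measures from named
  AP landmarks: extrusion index (EI), lateral center-edge angle (LCEA),
  acetabular index (AI), acetabular angle (AA), crossover ratio, and
  posterior wall distance (PWD, the signed horizontal distance from the
  head center to the posterior wall — negative when the wall is medial,
  i.e. posteriorly deficient), plus the obturator-index film-adequacy
  screen.
* **`hipcov.stats`** — pooled t-tests, ICC(2,1) observer reliability
  with Landis–Koch interpretation, and simple regression / Pearson
  correlation of 2D measures against 3D coverage.
* **`hipcov.synthetic_hip`** — a parametric hip generator (femur mesh,
  rim curve, simulated AP landmarks, multi-reader cohorts) with analytic
  and Monte-Carlo ground truth: a concentric cup of polar half-angle
  θc covers exactly `100·(1 − cos θc)/2` percent of the head, which
  anchors the whole chain to closed forms.
* **`hipcov.pipeline`** — cohort orchestration producing descriptive,
  reliability and regression tables plus the PWD-vs-posterior-coverage
  figure.

Meshes are handled with `trimesh` (PLY/STL/OBJ); rim curves are JSON/CSV
point lists; landmarks are a documented JSON schema. Coordinates are mm
in a right-hip frame (+x lateral, +y anterior, +z superior), and rim
curves are ordered counterclockwise seen from the acetabular side. See
`docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from hipcov import HipParams, generate_hip, full_coverage, measure_all
from hipcov.synthetic_hip import project_to_radiograph

# a retroverted hip: cranial version -12 deg, hemispheric socket
params = HipParams(cup_version=-12.0, cup_depth_angle=90.0)
mesh, rim, truth = generate_hip(params, seed=1)

report, diag = full_coverage(mesh, rim)
print("total coverage: %.1f%% (ground truth %.1f%%)"
      % (report.percent["TC"], truth.expected_total_coverage_pct))
for region in ("AL", "AM", "PL", "PM"):
    print("  %s: %5.1f%%  (oracle %5.1f%%)"
          % (region, report.percent[region],
             truth.expected_region_coverage_pct[region]))

landmarks = project_to_radiograph(mesh, rim)
m = measure_all(landmarks)
print("LCEA %.1f deg  EI %.2f  PWD %+.1f mm  crossover ratio %s"
      % (m.lcea, m.extrusion_index, m.posterior_wall_distance,
         "absent" if m.crossover_ratio is None else "%.2f" % m.crossover_ratio))
```

prints

```
total coverage: 49.7% (ground truth 50.0%)
  AL:   4.7%  (oracle   5.0%)
  AM:  96.0%  (oracle  96.4%)
  PL:   1.7%  (oracle   2.0%)
  PM:  96.5%  (oracle  96.7%)
LCEA 46.6 deg  EI 0.11  PWD -3.1 mm  crossover ratio 0.58
```

The mesh pipeline recovers the generator's ground truth to a few tenths
of a percentage point; the retroverted socket shows the expected
posterolateral deficit (PL ≈ 2%), a negative posterior wall distance,
and a positive crossover sign.

### Command line

```
hipcov synth hip --config hip.yaml --seed 1 --out hip/       # femur.ply, rim.json, ground_truth.json
hipcov coverage --femur hip/femur.ply --rim hip/rim.json --out report.json
hipcov measures --landmarks landmarks.json
hipcov synth cohort --config cohort.yaml --out cohort/
hipcov run --seed 7 --out results/                           # tables 1-3 + figure
```

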