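"""3D coverage chain: curvature, junction, regions, rim projection,
covered-area classification."""
import numpy as np
import pytest
import trimesh

from hipcov._geom import Plane
from hipcov.coverage3d import (
    JunctionDetectionError,
    RimCurve,
    covered_region,
    coverage_report,
    detect_head_neck_junction,
    estimate_curvature,
    fit_head_sphere,
    full_coverage,
    narrowest_neck_center,
    partition_head,
    project_rim,
    region_planes,
)
from hipcov.synthetic_hip import HipParams, generate_mesh, make_rim

from conftest import grid_cylinder


def sdf_mesh(sdf, bounds, pitch):
    from skimage.measure import marching_cubes

    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    ns = [int(np.ceil((hi[i] - lo[i]) / pitch)) + 1 for i in range(3)]
    axes = [lo[i] + pitch * np.arange(ns[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vol = sdf(grid).reshape(ns)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    mesh = trimesh.Trimesh(verts + lo, faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


class TestCurvature:
    def test_sphere(self, sphere_mesh):
        curv = estimate_curvature(sphere_mesh)
        k = 1.0 / 24.0
        assert np.median(curv.k1) == pytest.approx(k, rel=0.05)
        assert np.median(curv.k2) == pytest.approx(k, rel=0.05)

    def test_cylinder(self):
        cyl = grid_cylinder(radius=15.0, height=60.0)
        curv = estimate_curvature(cyl)
        core = np.abs(cyl.vertices[:, 2]) < 20.0  # away from the open ends
        assert np.median(curv.k1[core]) == pytest.approx(1.0 / 15.0, rel=0.05)
        assert abs(np.median(curv.k2[core])) < 0.005

    def test_saddle_sign_structure(self):
        n = 41
        x = np.linspace(-10, 10, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        zz = (xx**2 - yy**2) / 50.0
        verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + n, a + 1])
                faces.append([a + n, a + n + 1, a + 1])
        mesh = trimesh.Trimesh(verts, faces, process=False)
        curv = estimate_curvature(mesh)
        apex = int(np.argmin(np.linalg.norm(verts[:, :2], axis=1)))
        assert curv.k1[apex] > 0 > curv.k2[apex]


class TestHeadSphere:
    def test_recovers_generator_head(self, default_femur, default_params):
        center, radius, rms = fit_head_sphere(default_femur)
        assert np.linalg.norm(center - default_params.center) < 0.3
        assert radius == pytest.approx(default_params.head_radius, abs=0.3)
        assert rms < 0.5


class TestJunction:
    def test_detected_near_analytic_tangency(self, default_femur, default_params):
        sphere = fit_head_sphere(default_femur)
        edge = float(default_femur.edges_unique_length.mean())
        c1 = estimate_curvature(default_femur, 2.0 * edge)
        c2 = estimate_curvature(default_femur, 3.5 * edge)
        jr = detect_head_neck_junction(
            default_femur, c1, sphere, curv_coarse=c2, radii=(2.0 * edge, 3.5 * edge)
        )
        d = default_params.neck_direction
        t_axis = ((jr.plane.point - default_params.center) @ jr.plane.normal) / (
            d @ jr.plane.normal
        )
        assert abs(t_axis - default_params.junction_offset) < 2.0
        assert abs(jr.plane.normal @ d) > 0.99
        # head side keeps the apex and drops the shaft
        assert jr.head_mesh.vertices[:, 2].min() > default_femur.vertices[:, 2].min() + 30

    def test_isolated_sphere_has_no_inflection_ring(self, sphere_mesh):
        sphere = fit_head_sphere(sphere_mesh)
        curv = estimate_curvature(sphere_mesh)
        with pytest.raises(JunctionDetectionError, match="inflection"):
            detect_head_neck_junction(
                sphere_mesh, curv, sphere, neck_direction=np.array([1.0, 0, 0])
            )


class TestNeckCenter:
    def test_cylindrical_neck_section(self, default_femur, default_params):
        p = default_params
        center = narrowest_neck_center(
            default_femur, p.center, p.neck_direction, t_range=(22.0, 30.0)
        )
        # centroid should sit on the neck axis
        rel = center - p.center
        t = rel @ p.neck_direction
        off_axis = np.linalg.norm(rel - t * p.neck_direction)
        assert off_axis < 0.5

    def test_hourglass_minimum_found_and_step_stable(self):
        def hourglass(pts):
            r = 10.0 + 0.02 * pts[:, 2] ** 2
            return np.linalg.norm(pts[:, :2], axis=1) - r

        mesh = sdf_mesh(hourglass, ([-16, -16, -25], [16, 16, 25]), 1.0)
        c1 = narrowest_neck_center(
            mesh, np.array([0.0, 0, -20.0]), np.array([0.0, 0, 1.0]), (2.0, 38.0), 0.5
        )
        c2 = narrowest_neck_center(
            mesh, np.array([0.0, 0, -20.0]), np.array([0.0, 0, 1.0]), (2.0, 38.0), 0.25
        )
        assert abs(c1[2]) < 0.5
        assert np.linalg.norm(c1 - c2) < 0.5


class TestRegionPlanes:
    def test_hand_example(self):
        p1, p2 = region_planes((0.0, 0, 0), (30.0, 0, -20.0), (40.0, 0, -100.0))
        assert np.allclose(p1.normal, [0, 1, 0], atol=1e-12)
        expected = np.array([-30.0, 0, 20.0])
        expected /= np.linalg.norm(expected)
        assert np.allclose(p2.normal, expected, atol=1e-12)
        assert abs(p1.normal @ p2.normal) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            region_planes((0, 0, 0), (1.0, 0, 0), (2.0, 0, 0))


class TestPartition:
    def test_center_planes_quarter_the_sphere(self, sphere_mesh):
        planes = (
            Plane(np.zeros(3), [0, 1.0, 0]),
            Plane(np.zeros(3), [-1.0, 0, 0]),
        )
        part = partition_head(sphere_mesh, planes)
        areas = {r: part.region_area(r) for r in ("AL", "AM", "PL", "PM")}
        quarter = sphere_mesh.area / 4.0
        for a in areas.values():
            assert a == pytest.approx(quarter, rel=0.005)
        total = sum(areas.values())
        assert total == pytest.approx(part.mesh.area, rel=1e-12)
        assert total == pytest.approx(sphere_mesh.area, rel=1e-9)

    def test_offset_plane_shifts_areas_conserving_total(self, sphere_mesh):
        planes = (
            Plane(np.zeros(3), [0, 1.0, 0]),
            Plane(np.array([5.0, 0, 0]), [-1.0, 0, 0]),  # shifted 5 mm laterally
        )
        part = partition_head(sphere_mesh, planes)
        lat = part.region_area("AL") + part.region_area("PL")
        med = part.region_area("AM") + part.region_area("PM")
        # lateral cap beyond x = 5: zone area 2*pi*R*h with h = R - 5
        expected_lat = 2 * np.pi * 24.0 * (24.0 - 5.0)
        assert lat == pytest.approx(expected_lat, rel=0.01)
        assert lat < med
        assert lat + med == pytest.approx(sphere_mesh.area, rel=1e-9)

    def test_non_perpendicular_planes_rejected(self, sphere_mesh):
        with pytest.raises(ValueError):
            partition_head(
                sphere_mesh,
                (Plane(np.zeros(3), [0, 1.0, 0]), Plane(np.zeros(3), [0, 1.0, 0.2])),
            )


class TestRimProjection:
    def test_concentric_rim_projects_radially(self, sphere_mesh):
        p = HipParams(cup_depth_angle=90.0, cup_version=0.0, cup_inclination=0.0,
                      base_version=0.0, rim_wave_deg=0.0)
        curve = project_rim(make_rim(p), sphere_mesh)
        # projected points lie near the great circle x = 0 (cup axis -x)
        axis_dist = np.abs(curve[:, 0])
        edge = float(sphere_mesh.edges_unique_length.mean())
        assert axis_dist.max() < edge

    def test_radial_scaling_invariance(self, sphere_mesh):
        """Moving the rim radially outward leaves its projection onto the
        head unchanged (up to the facet sag of the discretized sphere)."""
        base = HipParams(cup_depth_angle=80.0)
        scaled = HipParams(cup_depth_angle=80.0, cup_radius=base.cup_radius + 5.0)
        c1 = project_rim(make_rim(base), sphere_mesh)
        c2 = project_rim(make_rim(scaled), sphere_mesh)
        from scipy.spatial import cKDTree

        hausdorff = max(
            cKDTree(c2).query(c1)[0].max(), cKDTree(c1).query(c2)[0].max()
        )
        assert hausdorff < 0.25

    def test_distant_rim_rejected(self, sphere_mesh):
        pts = np.column_stack(
            [500 + 30 * np.cos(np.linspace(0, 2 * np.pi, 32, endpoint=False)),
             30 * np.sin(np.linspace(0, 2 * np.pi, 32, endpoint=False)),
             np.zeros(32)]
        )
        from hipcov.coverage3d import CoverageError

        with pytest.raises(CoverageError):
            project_rim(RimCurve(pts), sphere_mesh)


class TestCoveredArea:
    @pytest.mark.parametrize("depth,expected", [(60.0, 25.0), (90.0, 50.0)])
    def test_concentric_cap_fraction(self, sphere_mesh, depth, expected):
        p = HipParams(cup_depth_angle=depth, cup_version=0.0, cup_inclination=0.0,
                      base_version=0.0, rim_wave_deg=0.0)
        planes = (p.region_plane_ap, p.region_plane_ml)
        part = partition_head(sphere_mesh, planes)
        rim = make_rim(p)
        curve = project_rim(rim, part.mesh)
        sphere = (np.zeros(3), 24.0, 0.0)
        cls = covered_region(part.mesh, curve, sphere, rim)
        rep = coverage_report(part, cls, sphere)
        assert rep.percent["TC"] == pytest.approx(expected, abs=1.0)

    def test_rotation_invariance_of_total_coverage(self, sphere_mesh):
        """Rotating a concentric cup moves coverage between regions but
        leaves the total unchanged."""
        sphere = (np.zeros(3), 24.0, 0.0)
        tcs = []
        for version, incl in [(0, 0), (10, 30), (-10, 50), (20, 45)]:
            p = HipParams(cup_depth_angle=75.0, cup_version=version, base_version=version,
                          cup_inclination=incl, rim_wave_deg=0.0)
            planes = (p.region_plane_ap, p.region_plane_ml)
            part = partition_head(sphere_mesh, planes)
            rim = make_rim(p)
            curve = project_rim(rim, part.mesh)
            cls = covered_region(part.mesh, curve, sphere, rim)
            rep = coverage_report(part, cls, sphere)
            tcs.append(rep.percent["TC"])
        closed = 100 * (1 - np.cos(np.radians(75.0))) / 2
        assert np.max(np.abs(np.asarray(tcs) - closed)) < 0.5

    def test_lateral_tilt_shifts_coverage_toward_lateral_regions(self, sphere_mesh):
        """Tilting a hemispheric cup toward the lateral side moves covered
        area from the medial to the lateral regions while the total stays
        at the cap fraction."""
        sphere = (np.zeros(3), 24.0, 0.0)
        shares = {}
        for incl in (10.0, -10.0):  # axis tilted superiorly vs inferiorly
            p = HipParams(cup_depth_angle=90.0, cup_version=0.0, base_version=0.0,
                          cup_inclination=incl, rim_wave_deg=0.0)
            planes = (p.region_plane_ap, p.region_plane_ml)
            part = partition_head(sphere_mesh, planes)
            rim = make_rim(p)
            cls = covered_region(part.mesh, project_rim(rim, part.mesh), sphere, rim)
            rep = coverage_report(part, cls, sphere)
            shares[incl] = rep
            assert rep.percent["TC"] == pytest.approx(50.0, abs=1.0)
        # the -10 deg cup axis points more toward the (neck-side) lateral
        # cone, so lateral regions gain and medial regions lose
        assert shares[-10.0].percent["AL"] > shares[10.0].percent["AL"]
        assert shares[-10.0].percent["PL"] > shares[10.0].percent["PL"]
        assert shares[-10.0].percent["AM"] < shares[10.0].percent["AM"]

    def test_rim_sampling_density_stability(self, sphere_mesh):
        p = HipParams(cup_depth_angle=85.0)
        rim = make_rim(p)
        sphere = (np.zeros(3), 24.0, 0.0)
        planes = (p.region_plane_ap, p.region_plane_ml)
        part = partition_head(sphere_mesh, planes)
        tc = {}
        for n in (256, 1024):
            curve = project_rim(rim, part.mesh, n_samples=n)
            cls = covered_region(part.mesh, curve, sphere, rim)
            tc[n] = coverage_report(part, cls, sphere).percent["TC"]
        assert abs(tc[256] - tc[1024]) < 0.2


class TestFullChain:
    def test_matches_ground_truth_regions(self, default_femur, default_params, default_rim):
        from hipcov.synthetic_hip import monte_carlo_region_coverage

        report, diag = full_coverage(default_femur, default_rim)
        mc = monte_carlo_region_coverage(default_params, 1 << 20, seed=11)
        for reg in ("AL", "AM", "PL", "PM", "Ant", "Post", "TC"):
            assert report.percent[reg] == pytest.approx(mc[reg], abs=1.5)

    def test_solid_angle_conservation(self, default_femur, default_rim):
        report, _ = full_coverage(default_femur, default_rim)
        total_cov = sum(report.covered_mm2[r] for r in ("AL", "AM", "PL", "PM"))
        assert report.covered_mm2["TC"] == pytest.approx(total_cov, rel=1e-12)
        mesh_total = sum(report.mesh_area_mm2[r] for r in ("AL", "AM", "PL", "PM"))
        assert report.mesh_area_mm2["TC"] == pytest.approx(mesh_total, rel=1e-12)
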