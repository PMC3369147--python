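"""Total and regional femoral-head coverage from a femur surface mesh and
an acetabular rim curve.

The measurement chain mirrors standard CT-based hip morphometry:

1. fit a sphere to the femoral head;
2. estimate per-vertex principal curvatures by local quadric fitting;
3. locate the head--neck junction as the ring where the minimum principal
   curvature crosses zero (the convex head turns into the saddle-shaped
   neck), fit a plane to it, and cut the head off along that plane;
4. build two perpendicular planes through the head center -- one through
   head / narrowest-neck / shaft centers (anterior-posterior divider) and
   one perpendicular to it (medial-lateral divider) -- giving four regions:
   anterolateral (AL), anteromedial (AM), posterolateral (PL),
   posteromedial (PM);
5. project the acetabular rim to its nearest points on the head to obtain
   the boundary of the covered region, classify head faces against that
   closed spherical curve, and report percent coverage per region.

Percentages are normalized by the full fitted-sphere reference areas
(4*pi*R^2 total, pi*R^2 per quadrant): two perpendicular planes through the
center always quarter a sphere, so a concentric cup of polar half-angle
theta_c yields total coverage 100*(1-cos theta_c)/2 irrespective of where
the junction cut lands. Covered areas are measured on the (junction-cut)
head mesh via per-face solid angles about the fitted center.

Meshes are `trimesh.Trimesh` objects with coordinates in mm in the
right-hip anatomical frame (+x lateral, +y anterior, +z superior).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from trimesh.intersections import slice_mesh_plane

from ._geom import Plane, fit_plane, fit_sphere, spherical_polygon_contains, unit

__all__ = [
    "RimCurve",
    "CurvatureField",
    "JunctionResult",
    "PartitionedHead",
    "CoverageClassification",
    "RegionCoverage",
    "JunctionDetectionError",
    "CoverageError",
    "fit_sphere",
    "fit_head_sphere",
    "estimate_curvature",
    "detect_head_neck_junction",
    "narrowest_neck_center",
    "region_planes",
    "partition_head",
    "project_rim",
    "covered_region",
    "coverage_report",
    "full_coverage",
]

REGIONS = ("AL", "AM", "PL", "PM")


class JunctionDetectionError(RuntimeError):
    """Raised when no circumferential inflection ring can be found."""


class CoverageError(RuntimeError):
    """Raised when the coverage boundary cannot be classified."""


class RimCurve:
    """Ordered closed sequence of acetabular-rim points with a periodic
    cubic spline through them.

    Parameters
    ----------
    points : (n, 3) array
        Ordered rim points in mm. The curve is closed implicitly; a
        duplicated first/last point is tolerated and removed.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("rim points must be (n, 3)")
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            raise ValueError("rim needs at least 8 control points")
        self.points = pts
        # chord-length parameterization, closed by wrapping to the start
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("duplicate consecutive rim points")
        t = np.concatenate([[0.0], np.cumsum(seg)])
        self._period = t[-1]
        self._spline = CubicSpline(t, closed, axis=0, bc_type="periodic")

    def sample(self, n: int = 512) -> np.ndarray:
        """``n`` points evenly spaced in spline parameter (excludes the
        duplicate closing point)."""
        t = np.linspace(0.0, self._period, n, endpoint=False)
        return self._spline(t)

    @property
    def centroid(self) -> np.ndarray:
        return self.sample(1024).mean(axis=0)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (1/mm), k1 >= k2."""

    k1: np.ndarray
    k2: np.ndarray
    flagged: np.ndarray  # vertices whose quadric fit was under-determined


@dataclass
class JunctionResult:
    inflection_points: np.ndarray
    plane: Plane
    head_mesh: trimesh.Trimesh


@dataclass
class PartitionedHead:
    """Head mesh with faces split along both region planes and labelled."""

    mesh: trimesh.Trimesh
    labels: np.ndarray  # region name per face
    plane_ap: Plane  # anterior/posterior divider (normal points anterior)
    plane_ml: Plane  # lateral/medial divider (normal points medial)

    def region_area(self, region: str) -> float:
        return float(self.mesh.area_faces[self.labels == region].sum())


@dataclass
class CoverageClassification:
    """Per-face covered fractions plus face measures about the head center."""

    covered_fraction: np.ndarray  # in [0, 1] per face
    solid_angles: np.ndarray  # signed steradians per face
    face_areas: np.ndarray  # mm^2 per face


@dataclass
class RegionCoverage:
    """Covered/total areas (mm^2) and percent coverage per region plus the
    TC / Ant / Post aggregates. ``total_mm2`` are spherical reference areas
    (quadrants of the fitted head sphere); ``mesh_*`` fields are areas
    measured on the head mesh itself and obey exact conservation."""

    head_center: np.ndarray
    head_radius: float
    covered_mm2: dict[str, float]
    total_mm2: dict[str, float]
    percent: dict[str, float]
    mesh_area_mm2: dict[str, float]
    mesh_covered_mm2: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "head_center": [float(x) for x in self.head_center],
            "head_radius": float(self.head_radius),
            "percent": {k: float(v) for k, v in self.percent.items()},
            "covered_mm2": {k: float(v) for k, v in self.covered_mm2.items()},
            "total_mm2": {k: float(v) for k, v in self.total_mm2.items()},
        }


# ---------------------------------------------------------------------------
# head sphere


def fit_head_sphere(mesh: trimesh.Trimesh, seed_radius: float = 15.0, n_iter: int = 6):
    """Robustly fit a sphere to the femoral head of a proximal femur mesh.

    Seeds from the superior-most vertices (the head apex in the anatomical
    frame), then alternates fitting with residual-based re-selection over
    the whole mesh. Returns ``(center, radius, rms)`` of the final fit.
    """
    v = mesh.vertices.view(np.ndarray)
    top = v[:, 2].max()
    subset = v[v[:, 2] > top - seed_radius]
    if len(subset) < 10:
        raise ValueError("mesh has too few vertices near its superior pole")
    center, radius, _ = fit_sphere(subset)
    for _ in range(n_iter):
        resid = np.abs(np.linalg.norm(v - center, axis=1) - radius)
        keep = v[resid < max(0.08 * radius, 1.0)]
        if len(keep) < 10:
            break
        center, radius, rms = fit_sphere(keep)
    return center, radius, rms


# ---------------------------------------------------------------------------
# curvature


def estimate_curvature(
    mesh: trimesh.Trimesh, neighborhood_radius: float | None = None
) -> CurvatureField:
    """Principal curvatures per vertex by quadric fit in the tangent frame.

    For each vertex, neighbors within ``neighborhood_radius`` (default
    2.5x the mean edge length) are expressed in a local frame aligned with
    the outward vertex normal and a full quadric
    ``h = a u^2 + b uv + c v^2 + d u + e v + f`` is fit by least squares.
    Curvatures come from the shape operator of the fitted graph; the sign
    convention makes convex regions (e.g. a sphere seen from outside)
    positive. Vertices with fewer than 6 neighbors are flagged and their
    curvatures interpolated from their 1-ring.
    """
    v = mesh.vertices.view(np.ndarray)
    normals = mesh.vertex_normals.view(np.ndarray)
    if neighborhood_radius is None:
        neighborhood_radius = 2.5 * float(mesh.edges_unique_length.mean())
    tree = cKDTree(v)
    neighbor_lists = tree.query_ball_point(v, r=neighborhood_radius, workers=-1)

    n = len(v)
    k1 = np.full(n, np.nan)
    k2 = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)

    # tangent frames: t1 orthogonal to normal, t2 = n x t1
    ref = np.where(np.abs(normals[:, 0:1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    t1 = unit(np.cross(normals, ref))
    t2 = np.cross(normals, t1)

    for i in range(n):
        idx = neighbor_lists[i]
        if len(idx) < 7:
            idx = tree.query_ball_point(v[i], r=2.0 * neighborhood_radius)
        if len(idx) < 7:
            flagged[i] = True
            continue
        rel = v[idx] - v[i]
        u = rel @ t1[i]
        w = rel @ t2[i]
        h = rel @ normals[i]
        A = np.column_stack([u * u, u * w, w * w, u, w, np.ones(len(u))])
        try:
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - pathological
            flagged[i] = True
            continue
        a, b, c, d, e, _ = coef
        # first/second fundamental forms of the graph (u, w, h(u, w))
        E = 1.0 + d * d
        F = d * e
        G = 1.0 + e * e
        norm = np.sqrt(1.0 + d * d + e * e)
        L, M, N = 2.0 * a / norm, b / norm, 2.0 * c / norm
        det_I = E * G - F * F
        S = (
            np.array([[G * L - F * M, G * M - F * N], [E * M - F * L, E * N - F * M]])
            / det_I
        )
        ev = np.linalg.eigvals(S).real
        # h was measured along the outward normal: convex => h < 0 => flip
        ka, kb = -ev
        k1[i], k2[i] = (ka, kb) if ka >= kb else (kb, ka)

    if flagged.any():
        ok = ~flagged
        fill_tree = cKDTree(v[ok])
        _, nearest = fill_tree.query(v[flagged], k=min(6, ok.sum()))
        nearest = np.atleast_2d(nearest)
        k1[flagged] = k1[ok][nearest].mean(axis=1)
        k2[flagged] = k2[ok][nearest].mean(axis=1)
    return CurvatureField(k1=k1, k2=k2, flagged=flagged)


# ---------------------------------------------------------------------------
# head-neck junction


def _meridian_crossings(
    mesh: trimesh.Trimesh,
    k2_all: np.ndarray,
    center: np.ndarray,
    radius: float,
    d: np.ndarray,
    n_meridians: int,
) -> dict[int, np.ndarray]:
    """First k2 zero-crossing (positive -> non-positive) per azimuthal
    meridian bin, marching from the head apex toward the neck."""
    v = mesh.vertices.view(np.ndarray)
    rel = v - center
    dist = np.linalg.norm(rel, axis=1)
    near = dist < 2.0 * radius
    rel_n = rel[near] / dist[near, None]
    apex_dir = -d
    psi = np.arccos(np.clip(rel_n @ apex_dir, -1.0, 1.0))
    e1 = unit(np.cross(d, [0.0, 0.0, 1.0] if abs(d[2]) < 0.9 else [0.0, 1.0, 0.0]))
    e2 = np.cross(d, e1)
    phi = np.arctan2(rel_n @ e2, rel_n @ e1)
    k2 = k2_all[near]
    pts = v[near]

    bins = ((phi + np.pi) / (2.0 * np.pi) * n_meridians).astype(int) % n_meridians
    crossings: dict[int, np.ndarray] = {}
    thresh = 0.2 / radius
    for b in range(n_meridians):
        sel = np.where(bins == b)[0]
        if len(sel) < 3:
            continue
        order = sel[np.argsort(psi[sel])]
        kk = k2[order]
        seen_positive = False
        for j in range(len(order) - 1):
            if kk[j] > thresh:
                seen_positive = True
            if seen_positive and kk[j] > 0.0 >= kk[j + 1]:
                t = kk[j] / (kk[j] - kk[j + 1])
                crossings[b] = pts[order[j]] * (1 - t) + pts[order[j + 1]] * t
                break
    return crossings


def detect_head_neck_junction(
    mesh: trimesh.Trimesh,
    curv: CurvatureField,
    head_sphere,
    neck_direction: np.ndarray | None = None,
    n_meridians: int = 48,
    min_crossings: int = 8,
    curv_coarse: CurvatureField | None = None,
    radii: tuple[float, float] | None = None,
) -> JunctionResult:
    """Find the head--neck junction as the circumferential zero-crossing
    ring of the minimum principal curvature k2.

    Walking each meridian from the head apex (antipode of the neck
    direction) outward, the first sign change of k2 from positive (convex
    head) to negative (saddle at the junction) is located and linearly
    interpolated. A least-squares plane is fit to the crossing points with
    one MAD-based trim pass, and the mesh is cut along it, keeping the
    side containing the apex.

    The quadric curvature estimator smears the crossing proximally by an
    amount roughly proportional to its neighborhood radius. When a second
    curvature field at a larger radius is supplied (``curv_coarse`` with
    the two ``radii``), the crossing points are extrapolated linearly to
    zero neighborhood radius meridian-by-meridian, which removes most of
    that bias.
    """
    center, radius, _ = head_sphere
    if neck_direction is None:
        # area centroid sits toward the neck/shaft for a proximal femur
        neck_direction = mesh.triangles_center.T @ mesh.area_faces
        neck_direction = neck_direction / mesh.area - center
    d = unit(np.asarray(neck_direction, dtype=float))
    apex_dir = -d

    cross_fine = _meridian_crossings(mesh, curv.k2, center, radius, d, n_meridians)
    if curv_coarse is not None and radii is not None:
        r1, r2 = radii
        if not r2 > r1 > 0:
            raise ValueError("radii must satisfy 0 < fine < coarse")
        cross_coarse = _meridian_crossings(
            mesh, curv_coarse.k2, center, radius, d, n_meridians
        )
        fac = r1 / (r2 - r1)
        merged = []
        for b, p1 in cross_fine.items():
            p2 = cross_coarse.get(b)
            if p2 is not None and np.linalg.norm(p1 - p2) < 0.3 * radius:
                merged.append(p1 + fac * (p1 - p2))
            else:
                merged.append(p1)
        crossings = merged
    else:
        crossings = list(cross_fine.values())
    if len(crossings) < min_crossings:
        raise JunctionDetectionError(
            f"no inflection ring: only {len(crossings)} of {n_meridians} "
            "meridians produced a k2 zero-crossing"
        )
    crossings = np.asarray(crossings)
    plane = fit_plane(crossings)
    resid = np.abs(plane.signed_distance(crossings))
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = resid <= np.median(resid) + 2.0 * mad
        if keep.sum() >= min_crossings:
            plane = fit_plane(crossings[keep])
    # orient normal away from the head (toward the neck)
    apex_point = center + radius * apex_dir
    normal = plane.normal
    if plane.signed_distance(apex_point[None])[0] > 0:
        normal = -normal
    plane = Plane(plane.point, normal)
    head_mesh = slice_mesh_plane(
        mesh, plane_normal=-plane.normal, plane_origin=plane.point, cap=False
    )
    if head_mesh is None or len(head_mesh.faces) == 0:
        raise JunctionDetectionError("junction cut removed the entire mesh")
    return JunctionResult(inflection_points=crossings, plane=plane, head_mesh=head_mesh)


# ---------------------------------------------------------------------------
# neck / regions


def narrowest_neck_center(
    mesh: trimesh.Trimesh,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    t_range: tuple[float, float],
    step: float = 0.5,
) -> np.ndarray:
    """Centroid of the minimum-area cross-section perpendicular to an axis.

    Planes are sampled every ``step`` mm for offsets ``t`` in ``t_range``
    along ``axis_dir`` from ``axis_point``. Where a plane cuts several
    closed loops, the loop whose centroid is nearest the axis is used.
    """
    axis_point = np.asarray(axis_point, dtype=float)
    axis_dir = unit(np.asarray(axis_dir, dtype=float))
    best = None
    for t in np.arange(t_range[0], t_range[1] + 0.5 * step, step):
        origin = axis_point + t * axis_dir
        section = mesh.section(plane_origin=origin, plane_normal=axis_dir)
        if section is None:
            continue
        planar, T = section.to_2D()
        polys = planar.polygons_full
        if len(polys) == 0:
            continue
        cands = []
        for poly in polys:
            cen2 = np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0])
            cen3 = (T @ cen2)[:3]
            off = cen3 - origin
            off -= (off @ axis_dir) * axis_dir
            cands.append((np.linalg.norm(off), poly.area, cen3))
        cands.sort(key=lambda c: c[0])
        d_axis, area, cen3 = cands[0]
        if best is None or area < best[0]:
            best = (area, cen3)
    if best is None:
        raise ValueError("no cross-sections found along the given axis range")
    return best[1]


def region_planes(head_center, neck_center, shaft_center) -> tuple[Plane, Plane]:
    """The two perpendicular region planes through the head center.

    Plane 1 passes through the head center, the narrowest-neck center and
    the shaft center, with its normal oriented toward +anterior (+y).
    Plane 2 passes through the head center perpendicular to plane 1; its
    normal is the component of (head - neck) orthogonal to plane 1's
    normal, oriented toward +medial (-x lateral axis).
    """
    h = np.asarray(head_center, dtype=float)
    n = np.asarray(neck_center, dtype=float)
    s = np.asarray(shaft_center, dtype=float)
    normal1 = np.cross(n - h, s - h)
    if np.linalg.norm(normal1) < 1e-9:
        raise ValueError("head, neck and shaft centers are collinear")
    normal1 = unit(normal1)
    if normal1[1] < 0:
        normal1 = -normal1
    w = h - n
    w = w - (w @ normal1) * normal1
    if np.linalg.norm(w) < 1e-9:
        raise ValueError("degenerate medial direction")
    normal2 = unit(w)
    if normal2[0] > 0:  # +x is lateral; orient toward medial
        normal2 = -normal2
    return Plane(h, normal1), Plane(h, normal2)


def partition_head(head_mesh: trimesh.Trimesh, planes: tuple[Plane, Plane]) -> PartitionedHead:
    """Split head faces exactly along both planes and label the quadrants.

    Faces straddling a plane are geometrically split by the plane cut, so
    region areas sum to the head area to floating-point accuracy.
    """
    p1, p2 = planes
    if abs(p1.normal @ p2.normal) > 1e-9:
        raise ValueError("region planes must be perpendicular")
    pieces, labels = [], []
    for s1, name1 in ((1.0, "A"), (-1.0, "P")):
        half = slice_mesh_plane(
            head_mesh, plane_normal=s1 * p1.normal, plane_origin=p1.point, cap=False
        )
        if half is None or len(half.faces) == 0:
            continue
        for s2, name2 in ((-1.0, "L"), (1.0, "M")):
            quad = slice_mesh_plane(
                half, plane_normal=s2 * p2.normal, plane_origin=p2.point, cap=False
            )
            if quad is None or len(quad.faces) == 0:
                continue
            pieces.append(quad)
            labels.append(np.full(len(quad.faces), name1 + name2))
    mesh = trimesh.util.concatenate(pieces)
    return PartitionedHead(
        mesh=mesh, labels=np.concatenate(labels), plane_ap=p1, plane_ml=p2
    )


# ---------------------------------------------------------------------------
# rim projection and covered classification


def _closest_on_surface(mesh: trimesh.Trimesh, points: np.ndarray, k: int = 12):
    """Nearest point on the mesh surface for each query point.

    KD-tree over face centroids proposes ``k`` candidate faces; the exact
    point-triangle distance picks the winner.
    """
    points = np.asarray(points, dtype=float)
    tree = cKDTree(mesh.triangles_center)
    k = min(k, len(mesh.faces))
    _, cand = tree.query(points, k=k, workers=-1)
    cand = np.atleast_2d(cand)
    tris = mesh.triangles.view(np.ndarray)[cand.ravel()]
    q = np.repeat(points, k, axis=0)
    close = trimesh.triangles.closest_point(tris, q).reshape(len(points), k, 3)
    d2 = ((close - points[:, None, :]) ** 2).sum(axis=2)
    pick = d2.argmin(axis=1)
    rows = np.arange(len(points))
    return close[rows, pick], np.sqrt(d2[rows, pick])


def project_rim(
    rim: RimCurve, head_mesh: trimesh.Trimesh, n_samples: int = 512
) -> np.ndarray:
    """Project the rim spline to its nearest points on the head surface,
    yielding the closed boundary curve of acetabular coverage."""
    samples = rim.sample(n_samples)
    on_surface, dist = _closest_on_surface(head_mesh, samples)
    scale = float(head_mesh.extents.max())
    if dist.min() > 2.0 * scale:
        raise CoverageError(
            "rim is far from the mesh: wrong bone or mismatched units/frames"
        )
    # merge consecutive duplicates
    keep = np.ones(len(on_surface), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(on_surface, axis=0), axis=1) > 1e-9
    curve = on_surface[keep]
    if np.allclose(curve[0], curve[-1]):
        curve = curve[:-1]
    if len(curve) < 8:
        raise CoverageError("projected rim collapsed to too few points")
    return curve


def _subdivide_triangle(tri: np.ndarray, depth: int) -> np.ndarray:
    """4-way midpoint subdivision of one triangle, ``depth`` times."""
    tris = tri[None]
    for _ in range(depth):
        a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
        ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
        tris = np.concatenate(
            [
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
                np.stack([ab, bc, ca], axis=1),
            ]
        )
    return tris


def _covered_pole(curve_u: np.ndarray) -> np.ndarray:
    """Pole of the covered cap from the orientation of the boundary curve.

    Fits a plane to the unit-sphere curve and measures its total azimuth
    sweep about the plane normal; the covered side is the one from which
    the ordered curve appears counterclockwise (sweep +2*pi).
    """
    n = fit_plane(curve_u).normal
    ref = [0.0, 0.0, 1.0] if abs(n[2]) < 0.9 else [0.0, 1.0, 0.0]
    b1 = unit(np.cross(n, ref))
    b2 = np.cross(n, b1)
    az = np.arctan2(curve_u @ b2, curve_u @ b1)
    closed = np.append(az, az[0])
    d = np.diff(closed)
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    sweep = d.sum()
    if abs(sweep) < np.pi:
        raise CoverageError(
            "coverage boundary does not wind around its plane normal; "
            "cannot determine the covered side"
        )
    return n if sweep > 0 else -n


def covered_region(
    head_mesh: trimesh.Trimesh,
    curve: np.ndarray,
    head_sphere,
    rim: RimCurve,
    subdivision_depth: int = 2,
) -> CoverageClassification:
    """Classify head faces as covered/uncovered against the projected rim.

    Face vertices and the curve are mapped radially to the unit sphere
    about the fitted head center; a vertex is covered iff the geodesic arc
    from it to an interior witness direction crosses the curve an even
    number of times. The witness is the cap pole about which the ordered
    curve winds counterclockwise, so rim point sequences must be ordered
    counterclockwise as seen from the acetabular (covered) side; this
    stays valid for sockets deeper than a hemisphere, where the rim
    centroid would fall on the uncovered side. Faces with mixed vertices
    are midpoint-subdivided and their sub-faces classified by centroid,
    giving a fractional covered area.
    """
    center, radius, _ = head_sphere
    center = np.asarray(center, dtype=float)
    v = head_mesh.vertices.view(np.ndarray)
    faces = head_mesh.faces.view(np.ndarray)
    curve_u = unit(curve - center)
    d_in = _covered_pole(curve_u)

    vert_u = unit(v - center)
    inside_v = spherical_polygon_contains(vert_u, curve_u, d_in)
    f_in = inside_v[faces]
    n_in = f_in.sum(axis=1)
    frac = np.where(n_in == 3, 1.0, 0.0)
    mixed = np.where((n_in > 0) & (n_in < 3))[0]

    from ._geom import triangle_solid_angles

    tris = head_mesh.triangles.view(np.ndarray)
    omegas = triangle_solid_angles(tris, center)
    areas = head_mesh.area_faces.copy()

    if len(mixed) > 0:
        sub = np.concatenate(
            [_subdivide_triangle(tris[i], subdivision_depth) for i in mixed]
        )
        cents = unit(sub.mean(axis=1) - center)
        sub_in = spherical_polygon_contains(cents, curve_u, d_in)
        sub_om = triangle_solid_angles(sub, center)
        per = 4**subdivision_depth
        for j, i in enumerate(mixed):
            om = sub_om[j * per : (j + 1) * per]
            ins = sub_in[j * per : (j + 1) * per]
            tot = om.sum()
            frac[i] = float(om[ins].sum() / tot) if tot != 0 else 0.0
    return CoverageClassification(
        covered_fraction=frac, solid_angles=omegas, face_areas=areas
    )


def coverage_report(
    partition: PartitionedHead,
    classification: CoverageClassification,
    head_sphere,
) -> RegionCoverage:
    """Combine region labels with covered fractions into percent coverage.

    Per-region percent = 100 * covered solid angle / quadrant solid angle
    (pi); total coverage uses the full sphere (4*pi); the anterior and
    posterior aggregates use half-spheres (2*pi). Areas in mm^2 scale the
    solid angles by R^2.
    """
    center, radius, _ = head_sphere
    r2 = float(radius) ** 2
    om = classification.solid_angles
    fr = classification.covered_fraction
    areas = classification.face_areas
    labels = partition.labels

    covered_mm2, total_mm2, percent = {}, {}, {}
    mesh_area, mesh_cov = {}, {}
    for reg in REGIONS:
        sel = labels == reg
        if not sel.any():
            raise ValueError(f"region {reg} has zero faces")
        om_cov = float((om[sel] * fr[sel]).sum())
        covered_mm2[reg] = om_cov * r2
        total_mm2[reg] = np.pi * r2
        percent[reg] = 100.0 * om_cov / np.pi
        mesh_area[reg] = float(areas[sel].sum())
        mesh_cov[reg] = float((areas[sel] * fr[sel]).sum())

    groups = {
        "Ant": ("AL", "AM"),
        "Post": ("PL", "PM"),
    }
    for name, (a, b) in groups.items():
        covered_mm2[name] = covered_mm2[a] + covered_mm2[b]
        total_mm2[name] = 2.0 * np.pi * r2
        percent[name] = 100.0 * (covered_mm2[name] / total_mm2[name])
        mesh_area[name] = mesh_area[a] + mesh_area[b]
        mesh_cov[name] = mesh_cov[a] + mesh_cov[b]
    covered_mm2["TC"] = sum(covered_mm2[r] for r in REGIONS)
    total_mm2["TC"] = 4.0 * np.pi * r2
    percent["TC"] = 100.0 * covered_mm2["TC"] / total_mm2["TC"]
    mesh_area["TC"] = sum(mesh_area[r] for r in REGIONS)
    mesh_cov["TC"] = sum(mesh_cov[r] for r in REGIONS)

    return RegionCoverage(
        head_center=np.asarray(center, dtype=float),
        head_radius=float(radius),
        covered_mm2=covered_mm2,
        total_mm2=total_mm2,
        percent=percent,
        mesh_area_mm2=mesh_area,
        mesh_covered_mm2=mesh_cov,
    )


# ---------------------------------------------------------------------------
# end-to-end


@dataclass
class CoverageConfig:
    curvature_radius_factor: float = 2.0
    curvature_coarse_factor: float = 3.5
    rim_samples: int = 512
    neck_scan_step: float = 0.5
    neck_scan_extent: float = 18.0
    shaft_probe_mm: float = 12.0
    n_meridians: int = 48
    subdivision_depth: int = 2


def _shaft_center(mesh: trimesh.Trimesh, probe_mm: float) -> np.ndarray:
    z = float(mesh.vertices[:, 2].min()) + probe_mm
    section = mesh.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
    if section is None:
        raise ValueError("no shaft cross-section at probe height")
    planar, T = section.to_2D()
    polys = sorted(planar.polygons_full, key=lambda p: p.area)
    poly = polys[-1]
    cen = (T @ np.array([poly.centroid.x, poly.centroid.y, 0.0, 1.0]))[:3]
    return cen


def full_coverage(
    mesh: trimesh.Trimesh,
    rim: RimCurve,
    config: CoverageConfig | None = None,
):
    """Run the complete measurement chain on one femur.

    Returns ``(RegionCoverage, diagnostics)`` where diagnostics carries the
    fitted head sphere, the junction plane and the region planes.
    """
    cfg = config or CoverageConfig()
    sphere = fit_head_sphere(mesh)
    edge = float(mesh.edges_unique_length.mean())
    r_fine = cfg.curvature_radius_factor * edge
    r_coarse = cfg.curvature_coarse_factor * edge
    curv = estimate_curvature(mesh, r_fine)
    curv_coarse = estimate_curvature(mesh, r_coarse)
    junction = detect_head_neck_junction(
        mesh,
        curv,
        sphere,
        n_meridians=cfg.n_meridians,
        curv_coarse=curv_coarse,
        radii=(r_fine, r_coarse),
    )
    neck_axis = junction.plane.normal
    t0 = float(junction.plane.signed_distance(np.asarray(sphere[0])[None])[0])
    neck_center = narrowest_neck_center(
        mesh,
        np.asarray(sphere[0]),
        neck_axis,
        t_range=(-t0 + 1.0, -t0 + cfg.neck_scan_extent),
        step=cfg.neck_scan_step,
    )
    shaft_center = _shaft_center(mesh, cfg.shaft_probe_mm)
    planes = region_planes(sphere[0], neck_center, shaft_center)
    partition = partition_head(junction.head_mesh, planes)
    curve = project_rim(rim, partition.mesh, cfg.rim_samples)
    classification = covered_region(
        partition.mesh, curve, sphere, rim, cfg.subdivision_depth
    )
    report = coverage_report(partition, classification, sphere)
    diagnostics = {
        "head_sphere": sphere,
        "junction_plane": junction.plane,
        "neck_center": neck_center,
        "shaft_center": shaft_center,
        "plane_ap": planes[0],
        "plane_ml": planes[1],
        "n_inflection_points": len(junction.inflection_points),
        "head_mesh_area_mm2": float(partition.mesh.area),
        "covered_omega_total": float(
            (classification.solid_angles * classification.covered_fraction).sum()
        ),
    }
    return report, diagnostics
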