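"""Parametric synthetic hip geometry with analytic ground truth.

Generates watertight proximal-femur surface meshes (sphere head + neck and
shaft capsules, blended by an implicit union and extracted by marching
cubes), an acetabular rim curve on a concentric cup sphere, simulated
AP-radiograph landmarks by orthographic projection, and multi-reader
cohorts with per-landmark measurement noise.

Frame convention (right hip): +x lateral, +y anterior, +z superior, head
center at the origin by default, units mm.

The cup is concentric with the head (congruent joint), so ground-truth
coverage has closed forms. The rim is *not* a planar circle: a rigidly
rotated planar rim can never produce a radiographic crossover sign under
orthographic projection (its projection is a simple closed curve, and two
arcs of a simple closed curve cannot cross). The rim model therefore
carries (a) a first-harmonic polar modulation (anterior wall shallower,
as in normal anatomy), (b) for retroverted cups a posterosuperior-to-
posterior wall deficiency plus a smaller anterosuperior prominence, and
(c) a cranial version twist: ``cup_version`` describes the version of the
cranial rim segment while the socket's base orientation never drops below
a few degrees of anteversion. The base polar angle is recalibrated
numerically after shaping so that the rim always encloses exactly the
spherical-cap fraction (1 - cos theta_c)/2, keeping ground-truth total
coverage at its closed form 100*(1 - cos theta_c)/2.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import trimesh
from shapely.geometry import LineString
from skimage.measure import marching_cubes

from ._geom import Plane, rot_x, rot_y, rot_z, unit
from .coverage3d import RimCurve, fit_head_sphere
from .radiograph2d import RadiographLandmarks

__all__ = [
    "HipParams",
    "GroundTruth",
    "GroupSpec",
    "CohortSpec",
    "SubjectRecord",
    "generate_hip",
    "generate_mesh",
    "make_rim",
    "project_to_radiograph",
    "generate_cohort",
    "monte_carlo_region_coverage",
]

REGIONS = ("AL", "AM", "PL", "PM")


@dataclass(frozen=True)
class HipParams:
    """Geometric parameters of one synthetic hip (mm / degrees)."""

    head_radius: float = 24.0
    head_center: tuple = (0.0, 0.0, 0.0)
    neck_radius: float = 14.0
    neck_length: float = 34.0
    neck_shaft_angle: float = 130.0
    shaft_radius: float = 14.0
    shaft_length: float = 70.0
    cup_radius: float = 26.0
    cup_depth_angle: float = 95.0
    cup_version: float = 15.0
    base_version: float | None = None
    cup_inclination: float = 42.0
    cam_bump_height: float = 0.0
    rim_wave_deg: float = 6.0
    blend_radius: float = 3.0
    mesh_resolution: int = 12000

    def validate(self) -> None:
        if not (self.head_radius > self.neck_radius > 0):
            raise ValueError("need head_radius > neck_radius > 0")
        if not (0.0 < self.cup_depth_angle < 180.0):
            raise ValueError("cup_depth_angle must be in (0, 180)")
        if self.cup_radius < self.head_radius:
            raise ValueError("cup_radius must be >= head_radius (congruent joint)")
        if self.mesh_resolution < 500:
            raise ValueError("mesh_resolution must be >= 500 vertices")
        if self.shaft_radius <= 0 or self.neck_length <= 0 or self.shaft_length <= 0:
            raise ValueError("lengths and radii must be positive")
        _calibrated_theta0(self)  # raises if the rim shape is infeasible

    # -- derived geometry -------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.head_center, dtype=float)

    @property
    def neck_direction(self) -> np.ndarray:
        """Unit vector from the head center toward the shaft."""
        gamma = math.radians(180.0 - self.neck_shaft_angle)
        return np.array([math.sin(gamma), 0.0, -math.cos(gamma)])

    @property
    def junction_offset(self) -> float:
        """Distance from head center to the analytic sphere/neck-cylinder
        tangency circle along the neck axis."""
        return math.sqrt(self.head_radius**2 - self.neck_radius**2)

    @property
    def junction_plane(self) -> Plane:
        d = self.neck_direction
        return Plane(self.center + self.junction_offset * d, d)

    @property
    def inflection_offset(self) -> float:
        """Axial offset of the constructed surface's true zero-curvature
        ring: the circle where the toroidal fillet contacts the head
        sphere (equals the tangency offset when there is no fillet)."""
        if self.blend_radius <= 0:
            return self.junction_offset
        R, rn, k = self.head_radius, self.neck_radius, self.blend_radius
        return R * math.sqrt((R + k) ** 2 - (rn + k) ** 2) / (R + k)

    @property
    def cup_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(axis, e1, e2): polar axis of the socket at its *base*
        orientation (pointing into the socket, i.e. medially for a neutral
        cup) and in-rim basis with e1 superior-ish (phi = 0) and e2
        anterior-ish (phi = +90 deg). ``cup_version`` acts on the cranial
        rim through a twist (see ``rim_twist``), not on this base frame.
        """
        R = rot_z(self.effective_base_version) @ rot_y(self.cup_inclination)
        opening = R @ np.array([1.0, 0.0, 0.0])
        axis = -opening
        e1 = R @ np.array([0.0, 0.0, 1.0])
        e2 = np.cross(axis, e1)
        return axis, e1, e2

    @property
    def effective_base_version(self) -> float:
        """Version of the socket away from its cranial segment. Follows
        ``cup_version`` but never drops below +4 deg: even markedly
        retroverted acetabula keep a near-neutral inferior rim, which is
        what lets the projected anterior and posterior walls keep their
        normal ordering caudally and cross cranially (the crossover
        sign). Explicitly settable via ``base_version``."""
        if self.base_version is not None:
            return self.base_version
        return float(np.clip(self.cup_version, 4.0, 18.0))

    def rim_twist(self, phi: np.ndarray) -> np.ndarray:
        """Azimuth-dependent version twist (radians, rotation about +z) of
        the rim: the cranial segment is rotated from the base version to
        ``cup_version``, emulating cranially focal (retro)version, which
        is what makes the projected rim fold into a figure-8 -- the
        radiographic crossover sign. A rigidly rotated planar-ish rim can
        never produce one."""
        phi = np.asarray(phi, dtype=float)
        d = (phi + np.pi) % (2.0 * np.pi) - np.pi  # distance from superior
        bump = np.exp(-((d / math.radians(55.0)) ** 2))
        return math.radians(self.cup_version - self.effective_base_version) * bump

    def rim_shape(self, phi: np.ndarray) -> np.ndarray:
        """Polar deviation g(phi) of the rim from its base depth angle: a
        first harmonic (anterior wall shallower, as in normal anatomy)
        plus, for retroverted cups, a posterosuperior wall deficiency and
        a smaller anterosuperior prominence growing with the amount of
        retroversion."""
        phi = np.asarray(phi, dtype=float)
        a1 = math.radians(self.rim_wave_deg)
        g = -a1 * np.sin(phi)
        retro = max(0.0, -self.cup_version)
        if retro > 0:
            D = math.radians(min(1.4 * retro, 26.0))
            A = 0.35 * D

            def bump(center_deg, sig_deg):
                d = (phi - math.radians(center_deg) + np.pi) % (2.0 * np.pi) - np.pi
                return np.exp(-((d / math.radians(sig_deg)) ** 2))

            g = g - D * bump(-85.0, 50.0) + A * bump(45.0, 45.0)
        return g

    @property
    def region_plane_ap(self) -> Plane:
        """Analytic anterior/posterior divider (head, neck and shaft
        centers are coplanar with y = 0 by construction)."""
        return Plane(self.center, np.array([0.0, 1.0, 0.0]))

    @property
    def region_plane_ml(self) -> Plane:
        d = self.neck_direction
        m = -d.copy()
        m[1] = 0.0
        return Plane(self.center, unit(m))


@dataclass(frozen=True)
class GroundTruth:
    """Analytic / Monte-Carlo oracle values for one synthetic hip."""

    expected_total_coverage_pct: float
    expected_region_coverage_pct: dict
    junction_plane: Plane
    true_version: float
    crossover_expected: bool
    cup_axis: np.ndarray
    total_from_mc: bool = False


# ---------------------------------------------------------------------------
# rim


def _rim_directions_at(params: HipParams, phi: np.ndarray, theta0: float) -> np.ndarray:
    """Unit directions of rim points for a given base polar angle."""
    axis, e1, e2 = params.cup_frame
    theta = theta0 + params.rim_shape(phi)
    dirs = (
        np.cos(theta)[:, None] * axis
        + np.sin(theta)[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    delta = params.rim_twist(phi)
    c, s = np.cos(delta), np.sin(delta)
    return np.column_stack(
        [c * dirs[:, 0] - s * dirs[:, 1], s * dirs[:, 0] + c * dirs[:, 1], dirs[:, 2]]
    )


def _enclosed_fraction(params: HipParams, theta0: float, n: int = 4096) -> float:
    """Fraction of the sphere enclosed by the rim curve (about the cup
    axis pole), by the spherical Green's theorem: (1/4pi) * closed
    integral of (1 - cos theta~) dphi~ in the base cup frame."""
    axis, e1, e2 = params.cup_frame
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    dirs = _rim_directions_at(params, phi, theta0)
    ct = np.clip(dirs @ axis, -1.0, 1.0)
    ph = np.arctan2(dirs @ e2, dirs @ e1)
    dph = np.diff(np.append(ph, ph[0]))
    dph = (dph + np.pi) % (2.0 * np.pi) - np.pi
    one_minus = 1.0 - ct
    mids = 0.5 * (one_minus + np.roll(one_minus, -1))
    return float((mids * dph).sum() / (4.0 * np.pi))


def _calibrated_theta0(params: HipParams) -> float:
    """Base polar angle solved so the rim encloses exactly the spherical
    cap fraction (1 - cos theta_c)/2 of a nominal cup of depth angle
    theta_c, keeping total coverage at its closed form for any rim shape
    or twist. Secant iteration; converges to ~1e-12 in a few steps."""
    target = (1.0 - math.cos(math.radians(params.cup_depth_angle))) / 2.0
    t0 = math.radians(params.cup_depth_angle)
    f0 = _enclosed_fraction(params, t0) - target
    t1 = t0 + 0.05
    f1 = _enclosed_fraction(params, t1) - target
    for _ in range(60):
        if f1 == f0:
            break
        t2 = t1 - f1 * (t1 - t0) / (f1 - f0)
        t0, f0, t1 = t1, f1, t2
        f1 = _enclosed_fraction(params, t1) - target
        if abs(f1) < 1e-13:
            break
    if abs(f1) > 1e-9 or not (0.0 < t1 < math.pi):
        raise ValueError("rim shape cannot be calibrated to the requested depth")
    return t1


def _rim_directions(params: HipParams, phi: np.ndarray) -> np.ndarray:
    return _rim_directions_at(params, phi, _calibrated_theta0(params))


def make_rim(params: HipParams, n_points: int = 96) -> RimCurve:
    """Ordered closed rim curve on the cup sphere."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    pts = params.center + params.cup_radius * _rim_directions(params, phi)
    return RimCurve(pts)


def _covered_mask(params: HipParams, dirs: np.ndarray, mask_junction=True) -> np.ndarray:
    """Whether unit directions from the head center are inside the cup cap
    (and on the head side of the analytic junction plane)."""
    axis, e1, e2 = params.cup_frame
    ct = dirs @ axis
    phi = np.arctan2(dirs @ e2, dirs @ e1)
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    # rim polar angle as a function of base-frame azimuth, from a dense
    # sample of the (possibly twisted) rim curve
    rphi_grid = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    rdirs = _rim_directions(params, rphi_grid)
    rph = np.arctan2(rdirs @ e2, rdirs @ e1)
    rth = np.arccos(np.clip(rdirs @ axis, -1.0, 1.0))
    order = np.argsort(rph)
    rph, rth = rph[order], rth[order]
    theta_rim = np.interp(phi, rph, rth, period=2.0 * np.pi)
    inside = theta <= theta_rim
    if mask_junction:
        d = params.neck_direction
        cos_cap = params.inflection_offset / params.head_radius
        inside &= (dirs @ d) <= cos_cap
    return inside


def _cup_touches_neck_cap(params: HipParams) -> bool:
    """Whether the covered region reaches the neck cap (checked as the
    minimum angular distance from rim points to the neck axis pole)."""
    d = params.neck_direction
    phi = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    dirs = _rim_directions(params, phi)
    sep_min = float(np.arccos(np.clip(dirs @ d, -1.0, 1.0)).min())
    cap = math.acos(params.inflection_offset / params.head_radius)
    return sep_min < cap


def monte_carlo_region_coverage(
    params: HipParams, n_samples: int = 1_000_000, seed: int = 0
) -> dict:
    """Monte-Carlo spherical-integration oracle for regional coverage.

    Uniform directions on the head sphere are classified by cup-cap
    membership, the analytic junction plane, and the two analytic region
    planes. Returns percent coverage per region plus TC/Ant/Post, each
    normalized by the full spherical quadrant the region belongs to.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5EED])
    dirs = rng.normal(size=(int(n_samples), 3))
    dirs = unit(dirs)
    covered = _covered_mask(params, dirs)
    ant = dirs @ params.region_plane_ap.normal > 0
    med = dirs @ params.region_plane_ml.normal > 0
    masks = {
        "AL": ant & ~med,
        "AM": ant & med,
        "PL": ~ant & ~med,
        "PM": ~ant & med,
    }
    out = {}
    for reg, m in masks.items():
        out[reg] = 100.0 * covered[m].sum() / m.sum()
    out["Ant"] = 100.0 * covered[ant].sum() / ant.sum()
    out["Post"] = 100.0 * covered[~ant].sum() / (~ant).sum()
    out["TC"] = 100.0 * covered.sum() / len(dirs)
    return out


# ---------------------------------------------------------------------------
# mesh


def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum: union with a tangency fillet of scale k."""
    if k <= 0:
        return np.minimum(a, b)
    h = np.maximum(k - np.abs(a - b), 0.0) / k
    return np.minimum(a, b) - 0.25 * k * h * h


def _sdf(params: HipParams, pts: np.ndarray) -> np.ndarray:
    c = params.center
    d = params.neck_direction
    p = pts - c
    k = params.blend_radius

    def capsule(a, b, r):
        ab = b - a
        t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
        proj = a + t[:, None] * ab
        return np.linalg.norm(pts - proj, axis=1) - r

    # head + neck joined by an exact toroidal tangency fillet of radius k:
    # in the (axial, radial) half-plane about the neck axis the boundary is
    # the sphere arc, a concave fillet arc tangent to both, then the
    # cylinder line. The fillet contacts the sphere on the circle at axial
    # offset R*t_cf/(R+k), just proximal to the sphere/cylinder tangency
    # circle, which is the analytic zero-crossing ring of k2.
    R, rn = params.head_radius, params.neck_radius
    neck_end = c + params.neck_length * d
    d_sphere = np.linalg.norm(p, axis=1) - R
    d_neck = capsule(c, neck_end, rn)
    sd = np.minimum(d_sphere, d_neck)
    if k > 0:
        t_ax = p @ d
        rho = np.linalg.norm(p - t_ax[:, None] * d, axis=1)
        q = np.array([math.sqrt((R + k) ** 2 - (rn + k) ** 2), rn + k])
        vA = -q * (k / (R + k))  # toward the sphere contact point
        vB = np.array([0.0, -k])  # toward the cylinder contact point
        v0 = t_ax - q[0]
        v1 = rho - q[1]
        sref = vA[0] * vB[1] - vA[1] * vB[0]
        c1 = (vA[0] * v1 - vA[1] * v0) * sref >= 0
        c2 = (v0 * vB[1] - v1 * vB[0]) * sref >= 0
        in_sector = c1 & c2
        sd = np.where(in_sector, k - np.hypot(v0, v1), sd)
    shaft_end = neck_end + np.array([0.0, 0.0, -params.shaft_length])
    sd = _smin(sd, capsule(neck_end, shaft_end, params.shaft_radius), k)
    if params.cam_bump_height > 0:
        rho = 8.0
        b_dir = unit(0.8 * d + 0.6 * np.array([0.0, 1.0, 0.0]))
        b_cen = c + (params.head_radius - rho + params.cam_bump_height) * b_dir
        sd = _smin(sd, np.linalg.norm(pts - b_cen, axis=1) - rho, k)
    return sd


def generate_mesh(params: HipParams) -> trimesh.Trimesh:
    """Extract the femur surface by marching cubes over the implicit union.

    The grid pitch is chosen from the analytic surface-area estimate to
    land near ``params.mesh_resolution`` vertices.
    """
    params.validate()
    c = params.center
    d = params.neck_direction
    neck_end = c + params.neck_length * d
    shaft_end = neck_end + np.array([0.0, 0.0, -params.shaft_length])
    r_max = max(params.head_radius, params.neck_radius, params.shaft_radius)
    lo = np.minimum.reduce([c - params.head_radius, neck_end - r_max, shaft_end - r_max])
    hi = np.maximum.reduce([c + params.head_radius, neck_end + r_max, shaft_end + r_max])
    pad = 3.0
    lo, hi = lo - pad, hi + pad

    area_est = (
        4.0 * np.pi * params.head_radius**2
        + 2.0 * np.pi * params.neck_radius * params.neck_length
        + 2.0 * np.pi * params.shaft_radius * params.shaft_length
    )
    pitch = math.sqrt(1.3 * area_est / params.mesh_resolution)
    pitch = min(pitch, params.head_radius / 4.0)

    nx, ny, nz = [max(8, int(np.ceil((hi[i] - lo[i]) / pitch)) + 1) for i in range(3)]
    xs = lo[0] + pitch * np.arange(nx)
    ys = lo[1] + pitch * np.arange(ny)
    zs = lo[2] + pitch * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    vol = _sdf(params, grid).reshape(nx, ny, nz)
    verts, faces, _, _ = marching_cubes(vol, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if len(mesh.vertices) < 500:
        raise ValueError("generated mesh has fewer than 500 vertices")
    return mesh


# ---------------------------------------------------------------------------
# crossover oracle (dense analytic projection, shapely intersection test)


def _project2d(points: np.ndarray, tilt: float, rotation: float, about: np.ndarray):
    R = rot_x(tilt) @ rot_z(rotation)
    q = (points - about) @ R.T + about
    return np.column_stack([q[:, 0], q[:, 2]]), q


WALL_GAP_DEG = 12.0  # un-traced rim azimuth near the superior and inferior poles


def _split_walls(rim3: np.ndarray, center: np.ndarray):
    """Index the dense closed rim into anterior-wall and posterior-wall
    arcs by rim-frame azimuth.

    Readers trace the two walls as distinct structures that do not reach
    the superior rim apex or the inferior notch, so each wall covers the
    rim azimuths from ``WALL_GAP_DEG`` to ``180 - WALL_GAP_DEG`` on its
    side (phi = 0 superior, +90 deg anterior, in the frame of the rim's
    best-fit plane with its normal pointing medially), ordered from the
    cranial end. Splitting one closed projected curve at its extreme
    points instead can never yield an interior wall crossing (two arcs of
    a simple closed curve meet only at their endpoints), which would make
    a crossover sign undetectable.
    """
    from ._geom import fit_plane

    rel = rim3 - center
    axis = fit_plane(rim3).normal
    if axis[0] > 0:  # orient toward medial (-x lateral axis, right hip)
        axis = -axis
    ref = np.array([0.0, 0.0, 1.0])
    e1 = unit(ref - (ref @ axis) * axis)  # superior in the rim plane
    e2 = np.cross(axis, e1)  # anterior-ish
    phi = np.degrees(np.arctan2(rel @ e2, rel @ e1))
    gap = WALL_GAP_DEG
    ant = np.where((phi > gap) & (phi < 180.0 - gap))[0]
    post = np.where((phi < -gap) & (phi > -180.0 + gap))[0]
    if len(ant) < 2 or len(post) < 2:
        raise ValueError("degenerate rim: cannot trace wall arcs")
    ant = ant[np.argsort(phi[ant])]  # cranial -> caudal
    post = post[np.argsort(-phi[post])]
    return ant, post


def _analytic_crossover(params: HipParams, n: int = 2048) -> bool:
    """Whether the projected anterior and posterior walls intersect at
    neutral pelvic orientation (independent dense-curve + shapely route)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rim3 = params.center + params.cup_radius * _rim_directions(params, phi)
    ant_idx, post_idx = _split_walls(rim3, params.center)
    img, _ = _project2d(rim3, 0.0, 0.0, params.center)
    return bool(LineString(img[ant_idx]).intersects(LineString(img[post_idx])))


# ---------------------------------------------------------------------------
# generate_hip


def generate_hip(params: HipParams, seed: int = 0):
    """Build one synthetic hip: femur mesh, rim curve and ground truth."""
    params.validate()
    mesh = generate_mesh(params)
    rim = make_rim(params)
    theta_c = math.radians(params.cup_depth_angle)
    closed_form = 100.0 * (1.0 - math.cos(theta_c)) / 2.0
    mc = monte_carlo_region_coverage(params, n_samples=1 << 20, seed=seed)
    touches = _cup_touches_neck_cap(params)
    gt = GroundTruth(
        expected_total_coverage_pct=(mc["TC"] if touches else closed_form),
        expected_region_coverage_pct={k: mc[k] for k in (*REGIONS, "Ant", "Post")},
        junction_plane=params.junction_plane,
        true_version=params.cup_version,
        crossover_expected=_analytic_crossover(params),
        cup_axis=params.cup_frame[0],
        total_from_mc=touches,
    )
    return mesh, rim, gt


# ---------------------------------------------------------------------------
# radiograph simulation


def project_to_radiograph(
    mesh: trimesh.Trimesh | None,
    rim: RimCurve,
    pelvic_tilt: float = 0.0,
    pelvic_rotation: float = 0.0,
    head_sphere=None,
    side: str = "right",
    n_rim_samples: int = 256,
    midline_offset: float = 95.0,
) -> RadiographLandmarks:
    """Simulate AP-radiograph landmarks by orthographic projection onto the
    coronal plane after applying pelvic tilt (about +x) and rotation
    (about +z).

    The head circle comes from the fitted head sphere (fit from the mesh
    when ``head_sphere`` is not given). The rim is split at its most
    lateral and medial projected points into anterior and posterior wall
    polylines. Synthetic pelvic landmarks (teardrops, obturator widths,
    horizontal reference) are emitted from a simple contralateral mirror
    model about a body midline ``midline_offset`` mm medial to the head.
    """
    if abs(pelvic_tilt) > 30 or abs(pelvic_rotation) > 30:
        raise ValueError("tilt/rotation must be within +/-30 degrees")
    if head_sphere is None:
        if mesh is None:
            raise ValueError("need either a mesh or an explicit head_sphere")
        head_sphere = fit_head_sphere(mesh)
    center, radius = np.asarray(head_sphere[0], dtype=float), float(head_sphere[1])

    rim3 = rim.sample(n_rim_samples)
    ant_idx, post_idx = _split_walls(rim3, center)
    img, _ = _project2d(rim3, pelvic_tilt, pelvic_rotation, center)
    i_lat = int(np.argmax(img[:, 0]))
    i_med = int(np.argmin(img[:, 0]))
    lateral_extent = img[i_lat, 0] - img[i_med, 0]
    if lateral_extent < 1e-6:
        raise ValueError("degenerate rim projection (rim plane edge-on)")

    c_img, _ = _project2d(center[None], pelvic_tilt, pelvic_rotation, center)
    c_img = c_img[0]
    lateral_rim = img[i_lat]
    # sourcil endpoints: support points of the projected rim in the
    # superolateral and superomedial 45-degree directions (the lateral
    # edge of the weight-bearing roof and its medial anchor)
    lateral_sourcil = img[int(np.argmax(img[:, 0] + img[:, 1]))]
    medial_sourcil = img[int(np.argmax(img[:, 1] - img[:, 0]))]

    # teardrop: inferomedial extreme of the rim
    i_td = int(np.argmin(img[:, 0] + img[:, 1]))
    teardrop3 = rim3[i_td]
    x_mid = center[0] - midline_offset
    teardrop3_contra = teardrop3 * np.array([0.0, 1.0, 1.0]) + np.array(
        [2.0 * x_mid - teardrop3[0], 0.0, 0.0]
    )
    td_img, _ = _project2d(teardrop3[None], pelvic_tilt, pelvic_rotation, center)
    tdc_img, _ = _project2d(teardrop3_contra[None], pelvic_tilt, pelvic_rotation, center)
    href = unit(td_img[0] - tdc_img[0])

    # obturator foramina: tilted horizontal chords, mirrored about midline
    o_cen = center + np.array([-40.0, 0.0, -68.0])
    o_dir = rot_z(-20.0) @ np.array([1.0, 0.0, 0.0]) * 15.0
    e_ipsi = np.stack([o_cen - o_dir, o_cen + o_dir])
    e_contra = e_ipsi.copy()
    e_contra[:, 0] = 2.0 * x_mid - e_contra[:, 0]
    wi_img, _ = _project2d(e_ipsi, pelvic_tilt, pelvic_rotation, center)
    wc_img, _ = _project2d(e_contra, pelvic_tilt, pelvic_rotation, center)
    width_ipsi = float(np.linalg.norm(wi_img[1] - wi_img[0]))
    width_contra = float(np.linalg.norm(wc_img[1] - wc_img[0]))

    ant = img[ant_idx]
    post = img[post_idx]
    return RadiographLandmarks(
        head_center=c_img,
        head_radius=radius,
        lateral_sourcil=lateral_sourcil,
        medial_sourcil=medial_sourcil,
        teardrop=td_img[0],
        teardrop_contralateral=tdc_img[0],
        lateral_rim=lateral_rim,
        anterior_wall=ant,
        posterior_wall=post,
        obturator_width_ipsi=width_ipsi,
        obturator_width_contra=width_contra,
        horizontal_ref=href,
        side=side,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group parameter distributions (means / SDs)."""

    version_mean: float
    version_sd: float
    version_max: float | None = None
    version_min: float | None = None
    depth_mean: float = 95.0
    depth_sd: float = 3.0
    inclination_mean: float = 42.0
    inclination_sd: float = 3.0
    head_radius_mean: float = 24.0
    head_radius_sd: float = 1.2


CONTROL_GROUP = GroupSpec(
    version_mean=15.0,
    version_sd=4.0,
    version_min=8.0,
    depth_mean=99.0,
    depth_sd=2.5,
    inclination_mean=41.0,
    inclination_sd=3.0,
)
PATIENT_GROUP = GroupSpec(
    version_mean=-11.0,
    version_sd=3.0,
    version_max=-6.0,
    depth_mean=90.0,
    depth_sd=2.5,
    inclination_mean=46.0,
    inclination_sd=3.0,
)


@dataclass(frozen=True)
class CohortSpec:
    """Study design: group sizes, parameter distributions, readers."""

    n_controls: int = 18
    n_patients: int = 16
    control: GroupSpec = CONTROL_GROUP
    patient: GroupSpec = PATIENT_GROUP
    n_readers: int = 2
    n_reads: int = 2
    reader_noise_sd: float = 0.6  # mm, per-read noise on landmark coordinates
    reader_bias_sd: float = 0.5  # mm, persistent per-(subject, reader) bias
    tilt_sd: float = 2.0
    rotation_sd: float = 1.5
    mesh_resolution: int = 12000
    seed: int = 0

    def validate(self) -> None:
        if self.n_readers < 1 or self.n_reads < 1:
            raise ValueError("need at least one reader and one read")
        if min(self.reader_noise_sd, self.reader_bias_sd, self.tilt_sd, self.rotation_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "control" | "patient"
    params: HipParams
    seed: int
    ground_truth: GroundTruth
    rim: RimCurve
    pelvic_tilt: float
    pelvic_rotation: float
    landmarks: dict  # (reader, read) -> RadiographLandmarks
    mesh: trimesh.Trimesh | None = None


def _draw_params(g: GroupSpec, rng: np.random.Generator, resolution: int) -> HipParams:
    version = rng.normal(g.version_mean, g.version_sd)
    if g.version_min is not None:
        version = max(version, g.version_min)
    if g.version_max is not None:
        version = min(version, g.version_max)
    head_r = float(np.clip(rng.normal(g.head_radius_mean, g.head_radius_sd), 20.0, 28.0))
    depth = float(np.clip(rng.normal(g.depth_mean, g.depth_sd), 70.0, 104.0))
    incl = float(np.clip(rng.normal(g.inclination_mean, g.inclination_sd), 30.0, 55.0))
    return HipParams(
        head_radius=head_r,
        neck_radius=0.58 * head_r,
        shaft_radius=0.58 * head_r,
        cup_radius=head_r + 2.0,
        cup_depth_angle=depth,
        cup_version=float(version),
        cup_inclination=incl,
        mesh_resolution=resolution,
    )


def _jitter_landmarks(
    lm: RadiographLandmarks, sd: float, rng: np.random.Generator
) -> RadiographLandmarks:
    """Reader noise: iid Normal(0, sd) on point landmarks, a rigid offset
    plus smaller per-vertex noise on wall polylines, and proportionally
    smaller noise on the radius and obturator widths."""
    if sd == 0:
        return lm

    def jp(p):
        return np.asarray(p) + rng.normal(0.0, sd, size=2)

    def jwall(w):
        return w + rng.normal(0.0, sd, size=2) + rng.normal(0.0, sd / 3.0, size=w.shape)

    return RadiographLandmarks(
        head_center=jp(lm.head_center),
        head_radius=max(1.0, lm.head_radius + rng.normal(0.0, sd / 2.0)),
        lateral_sourcil=jp(lm.lateral_sourcil),
        medial_sourcil=jp(lm.medial_sourcil),
        teardrop=jp(lm.teardrop),
        teardrop_contralateral=jp(lm.teardrop_contralateral),
        lateral_rim=jp(lm.lateral_rim),
        anterior_wall=jwall(lm.anterior_wall),
        posterior_wall=jwall(lm.posterior_wall),
        obturator_width_ipsi=max(1.0, lm.obturator_width_ipsi + rng.normal(0.0, sd / 2.0)),
        obturator_width_contra=max(
            1.0, lm.obturator_width_contra + rng.normal(0.0, sd / 2.0)
        ),
        horizontal_ref=lm.horizontal_ref,
        side=lm.side,
    )


def generate_cohort(
    spec: CohortSpec, include_meshes: bool = False, mc_samples: int = 1 << 20
) -> list[SubjectRecord]:
    """Draw a full two-group cohort, reproducible from ``spec.seed``.

    Controls are anteverted with deeper sockets; patients are retroverted
    with shallower, steeper sockets. Each subject gets one landmark set
    per (reader, read) with seeded landmark jitter. Meshes are attached
    only on request; they can always be regenerated deterministically via
    ``generate_mesh(record.params)``.
    """
    spec.validate()
    root = np.random.default_rng(int(spec.seed) & 0x7FFFFFFF)
    records: list[SubjectRecord] = []
    groups = [("control", spec.control)] * spec.n_controls + [
        ("patient", spec.patient)
    ] * spec.n_patients
    for i, (group, gspec) in enumerate(groups):
        sub_seed = int(root.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        params = _draw_params(gspec, rng, spec.mesh_resolution)
        tilt = float(np.clip(rng.normal(0.0, spec.tilt_sd), -12.0, 12.0))
        rotation = float(np.clip(rng.normal(0.0, spec.rotation_sd), -10.0, 10.0))
        rim = make_rim(params)
        mc = monte_carlo_region_coverage(params, n_samples=mc_samples, seed=sub_seed)
        theta_c = math.radians(params.cup_depth_angle)
        touches = _cup_touches_neck_cap(params)
        gt = GroundTruth(
            expected_total_coverage_pct=(
                mc["TC"] if touches else 100.0 * (1.0 - math.cos(theta_c)) / 2.0
            ),
            expected_region_coverage_pct={k: mc[k] for k in (*REGIONS, "Ant", "Post")},
            junction_plane=params.junction_plane,
            true_version=params.cup_version,
            crossover_expected=_analytic_crossover(params),
            cup_axis=params.cup_frame[0],
            total_from_mc=touches,
        )
        base_lm = project_to_radiograph(
            None,
            rim,
            pelvic_tilt=tilt,
            pelvic_rotation=rotation,
            head_sphere=(params.center, params.head_radius, 0.0),
        )
        # persistent per-reader bias (systematic digitization habits) plus
        # independent per-read noise: intra-observer agreement then exceeds
        # inter-observer agreement, as in real repeatability studies
        landmarks = {}
        for reader in range(spec.n_readers):
            reader_lm = _jitter_landmarks(base_lm, spec.reader_bias_sd, rng)
            for read in range(spec.n_reads):
                landmarks[(reader, read)] = _jitter_landmarks(
                    reader_lm, spec.reader_noise_sd, rng
                )
        mesh = generate_mesh(params) if include_meshes else None
        records.append(
            SubjectRecord(
                subject_id=f"{group[0].upper()}{i:03d}",
                group=group,
                params=params,
                seed=sub_seed,
                ground_truth=gt,
                rim=rim,
                pelvic_tilt=tilt,
                pelvic_rotation=rotation,
                landmarks=landmarks,
                mesh=mesh,
            )
        )
    return records
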