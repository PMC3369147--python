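"""Low-level geometric primitives shared across the package.

Everything here is frame-agnostic: rotations, planes, least-squares
circle/sphere fits, solid angles of triangles about an origin, and
point-in-spherical-polygon classification by geodesic crossing parity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v``; raises on zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalize zero vector")
    return v / n


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(np.asarray(self.normal, dtype=float)))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.point) @ self.normal


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through a 3D point cloud (SVD)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return Plane(centroid, vt[-1])


def fit_sphere(points: np.ndarray):
    """Least-squares sphere: algebraic (Pratt-style linear) seed followed by
    geometric (orthogonal-distance) refinement.

    Returns ``(center (3,), radius, rms_residual)``.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need >= 4 points in 3D")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate (coplanar or coincident) point set")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point set: non-positive squared radius")
    radius = float(np.sqrt(r2))

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    out = least_squares(resid, np.append(center, radius), method="lm")
    center, radius = out.x[:3], float(out.x[3])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def fit_circle(points: np.ndarray):
    """Least-squares circle in 2D; algebraic seed + geometric refinement.

    Returns ``(center (2,), radius, rms_residual)``.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
        raise ValueError("need >= 3 points in 2D")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("collinear points")
    center = sol[:2]
    r2 = sol[2] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point set")
    radius = float(np.sqrt(r2))

    def resid(x):
        return np.linalg.norm(p - x[:2], axis=1) - x[2]

    out = least_squares(resid, np.append(center, radius), method="lm")
    center, radius = out.x[:2], float(out.x[2])
    rms = float(np.sqrt(np.mean(resid(out.x) ** 2)))
    return center, radius, rms


def triangle_solid_angles(triangles: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Signed solid angle subtended at ``origin`` by each triangle.

    Van Oosterom & Strackee formula; sign follows vertex winding as seen
    from the origin. ``triangles`` has shape (n, 3, 3).
    """
    t = np.asarray(triangles, dtype=float) - np.asarray(origin, dtype=float)
    r1, r2, r3 = t[:, 0], t[:, 1], t[:, 2]
    l1 = np.linalg.norm(r1, axis=1)
    l2 = np.linalg.norm(r2, axis=1)
    l3 = np.linalg.norm(r3, axis=1)
    num = np.einsum("ij,ij->i", r1, np.cross(r2, r3))
    den = (
        l1 * l2 * l3
        + np.einsum("ij,ij->i", r1, r2) * l3
        + np.einsum("ij,ij->i", r1, r3) * l2
        + np.einsum("ij,ij->i", r2, r3) * l1
    )
    return 2.0 * np.arctan2(num, den)


def _arc_contains(a, b, n, w):
    """True where unit point ``w`` lies on the minor arc a->b (n = a x b).

    All arrays broadcast; a, b, n may be (..., 3).
    """
    c1 = np.einsum("...j,...j->...", np.cross(a, w), n) >= 0.0
    c2 = np.einsum("...j,...j->...", np.cross(w, b), n) >= 0.0
    return c1 & c2


def spherical_polygon_contains(
    points: np.ndarray,
    polygon: np.ndarray,
    interior: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Classify unit-sphere ``points`` against a closed spherical ``polygon``.

    A point is inside iff the minor geodesic arc from it to the known
    interior witness direction crosses the polygon an even number of
    times. All inputs must be unit vectors; the polygon is closed
    implicitly (last vertex connects to the first).
    """
    pts = unit(np.atleast_2d(points))
    poly = unit(np.atleast_2d(polygon))
    d = unit(np.asarray(interior, dtype=float))
    c = poly
    e = np.roll(poly, -1, axis=0)
    n2 = np.cross(c, e)  # (M, 3) edge great-circle normals
    good = np.linalg.norm(n2, axis=1) > 1e-15
    c, e, n2 = c[good], e[good], n2[good]

    inside = np.empty(len(pts), dtype=bool)
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]  # (N, 3)
        n1 = np.cross(p, d)  # (N, 3)
        w = np.cross(n1[:, None, :], n2[None, :, :])  # (N, M, 3)
        wn = np.linalg.norm(w, axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(wn > 1e-15, w / wn, 0.0)
        pN = p[:, None, :]
        dN = np.broadcast_to(d, pN.shape)
        n1N = n1[:, None, :]
        cN = c[None, :, :]
        eN = e[None, :, :]
        n2N = n2[None, :, :]
        hit = np.zeros(w.shape[:2], dtype=bool)
        for s in (1.0, -1.0):
            ws = s * w
            on1 = _arc_contains(pN, dN, n1N, ws)
            on2 = _arc_contains(cN, eN, n2N, ws)
            hit |= on1 & on2 & (wn[..., 0] > 1e-15)
        crossings = hit.sum(axis=1)
        inside[lo : lo + chunk] = crossings % 2 == 0
    return inside


def segment_intersection_2d(p, r, q, s):
    """Intersection parameters of segments p+t*r, q+u*s (t,u in [0,1]).

    Vectorized over the second segment: ``q``/``s`` may be (m, 2).
    Returns (t, u, valid) arrays.
    """
    p, r = np.asarray(p, float), np.asarray(r, float)
    q, s = np.atleast_2d(np.asarray(q, float)), np.atleast_2d(np.asarray(s, float))
    denom = r[0] * s[:, 1] - r[1] * s[:, 0]
    qp = q - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]) / denom
        u = (qp[:, 0] * r[1] - qp[:, 1] * r[0]) / denom
    valid = (np.abs(denom) > 1e-15) & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
    return t, u, valid


def polyline_first_intersection(a: np.ndarray, b: np.ndarray):
    """First intersection point walking polyline ``a`` from its start.

    Scans segments of ``a`` in order against all segments of ``b``;
    within an ``a`` segment the smallest parameter wins. Returns the
    intersection point (2,) or None.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        return None
    q = b[:-1]
    s = b[1:] - b[:-1]
    for i in range(len(a) - 1):
        p = a[i]
        r = a[i + 1] - a[i]
        t, _, valid = segment_intersection_2d(p, r, q, s)
        if valid.any():
            tmin = t[valid].min()
            return p + tmin * r
    return None
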