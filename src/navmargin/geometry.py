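"""Analytic geometric primitives used by the phantom generator.

Tumor bodies are unions of ellipsoids and the carotid is a constant-radius
tube swept along a cubic spline.  Everything downstream (clearance
calibration, ideal-plane construction, voxelization) needs exact
point-to-surface distances for these two primitives, so they are computed
analytically here rather than through any voxel grid.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ellipsoid_surface_distance",
    "Centerline",
    "min_distance_to_curve",
    "ellipsoid_mesh",
    "tube_mesh",
]


def ellipsoid_surface_distance(points, center, semi_axes):
    """Signed Euclidean distance from ``points`` to an ellipsoid surface.

    Negative inside, positive outside.  Uses the Lagrange formulation of
    the nearest-point problem: the foot point ``q`` of ``p`` satisfies
    ``q_i = a_i^2 p_i / (t + a_i^2)`` where ``t`` is the largest root of
    ``sum((a_i p_i / (t + a_i^2))^2) = 1`` on ``(-min(a)^2, inf)``.  The
    root is bracketed and solved by vectorized bisection, which is robust
    for both interior and exterior points.

    Parameters
    ----------
    points : (n, 3) array
        Query points, world mm.
    center : (3,) array
        Ellipsoid center, world mm.
    semi_axes : (3,) array
        Semi-axis lengths, mm.

    Returns
    -------
    (n,) array of signed distances in mm.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    if np.any(a <= 0):
        raise ValueError("semi-axes must be positive")
    # Degenerate coordinates (p_i == 0) make the Lagrange function
    # discontinuous; nudging off the symmetry plane changes the distance
    # by O(eps) only.
    p_abs = np.maximum(np.abs(p), 1e-9)
    r = np.linalg.norm(p_abs, axis=1)
    a_max = a.max()
    a_min2 = a.min() ** 2

    lo = np.full(r.shape, -a_min2 * (1.0 - 1e-12) - 1e-12)
    hi = 2.0 * np.sqrt(3.0) * a_max * (r + a_max)

    ap = a * p_abs  # (n, 3)
    a2 = a**2

    def f(t):
        return np.sum((ap / (t[:, None] + a2)) ** 2, axis=1) - 1.0

    for _ in range(64):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0.0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    t = 0.5 * (lo + hi)

    q = a2 * p_abs / (t[:, None] + a2)
    dist = np.linalg.norm(p_abs - q, axis=1)
    inside = np.sum((p_abs / a) ** 2, axis=1) < 1.0
    return np.where(inside, -dist, dist)


class Centerline:
    """Smooth space curve through control points (natural cubic spline).

    Parametrized by chord length of the control polygon; ``sample(step)``
    returns points approximately ``step`` mm apart along the curve.
    """

    def __init__(self, control_points):
        cp = np.asarray(control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[0] < 2 or cp.shape[1] != 3:
            raise ValueError("need at least two 3D control points")
        seg = np.linalg.norm(np.diff(cp, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("duplicate consecutive control points")
        self._u = np.concatenate([[0.0], np.cumsum(seg)])
        self._spline = CubicSpline(self._u, cp, axis=0)
        self.control_points = cp

    @property
    def length(self) -> float:
        return float(self._u[-1])

    def __call__(self, u):
        return self._spline(u)

    def tangent(self, u):
        d = self._spline(u, 1)
        d = np.atleast_2d(d)
        return np.squeeze(d / np.linalg.norm(d, axis=-1, keepdims=True))

    def sample(self, step: float):
        """Curve points spaced ~``step`` mm in parameter (chord) length."""
        n = max(int(np.ceil(self.length / step)) + 1, 2)
        u = np.linspace(0.0, self._u[-1], n)
        return self._spline(u)

    def translated(self, offset) -> "Centerline":
        return Centerline(self.control_points + np.asarray(offset, dtype=float))


def min_distance_to_curve(points, curve_points, chunk: int = 262144):
    """Minimum distance from each query point to a densely sampled curve.

    ``curve_points`` should be sampled finely enough (step ``h``) that the
    chord error ``h^2 / (8 rho)`` is below the needed tolerance.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cp = np.asarray(curve_points, dtype=float)
    out = np.empty(pts.shape[0])
    for i in range(0, pts.shape[0], chunk):
        block = pts[i : i + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            - 2.0 * block @ cp.T
            + np.sum(cp**2, axis=1)[None, :]
        )
        out[i : i + chunk] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return out


def point_mesh_distance(points, mesh, chunk: int = 64):
    """Unsigned distance from points to a triangle mesh (exact, brute force).

    For each point the minimum over all faces of the exact point-triangle
    distance (interior projection or nearest edge segment).  Quadratic in
    (points x faces); intended for shortlisted queries, not whole grids.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(mesh if isinstance(mesh, np.ndarray) else mesh.triangles, dtype=float)  # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    out = np.empty(pts.shape[0])
    for i in range(0, pts.shape[0], chunk):
        p = pts[i : i + chunk][:, None, :]  # (k, 1, 3)
        d2 = _point_triangle_sq(p, a[None], b[None], c[None])
        out[i : i + chunk] = np.sqrt(d2.min(axis=1))
    return out


def _point_segment_sq(p, s0, s1):
    d = s1 - s0
    t = np.sum((p - s0) * d, axis=-1) / np.maximum(np.sum(d * d, axis=-1), 1e-300)
    t = np.clip(t, 0.0, 1.0)
    proj = s0 + t[..., None] * d
    return np.sum((p - proj) ** 2, axis=-1)


def _point_triangle_sq(p, a, b, c):
    """Squared distance point-to-triangle, broadcasting (k,1,3)x(1,m,3)."""
    ab = b - a
    ac = c - a
    n = np.cross(ab, ac)
    nn = np.maximum(np.sum(n * n, axis=-1), 1e-300)
    ap = p - a
    # barycentric coordinates of the in-plane projection
    d00 = np.sum(ab * ab, axis=-1)
    d01 = np.sum(ab * ac, axis=-1)
    d11 = np.sum(ac * ac, axis=-1)
    d20 = np.sum(ap * ab, axis=-1)
    d21 = np.sum(ap * ac, axis=-1)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0.0) & (w >= 0.0) & (v + w <= 1.0)
    plane_sq = np.sum(ap * n, axis=-1) ** 2 / nn
    edge_sq = np.minimum(
        _point_segment_sq(p, a, b),
        np.minimum(_point_segment_sq(p, b, c), _point_segment_sq(p, a, c)),
    )
    return np.where(inside, plane_sq, edge_sq)


def ellipsoid_mesh(center, semi_axes, subdivisions: int = 4):
    """Watertight triangulated ellipsoid (subdivided icosahedron)."""
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.apply_scale(np.asarray(semi_axes, dtype=float))
    mesh.apply_translation(np.asarray(center, dtype=float))
    return mesh


def _transport_frames(points):
    """Parallel-transport orthonormal frames along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, tangents[0])) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    n = seed - np.dot(seed, tangents[0]) * tangents[0]
    normals[0] = n / np.linalg.norm(n)
    for i in range(1, len(points)):
        n = normals[i - 1] - np.dot(normals[i - 1], tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return normals, binormals


def tube_mesh(curve_points, radius: float, sections: int = 48):
    """Watertight tube of constant ``radius`` swept along a polyline.

    Cross-sections use parallel-transport frames (no torsion flips); the
    ends are closed with triangle fans.
    """
    import trimesh

    pts = np.asarray(curve_points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two curve points")
    normals, binormals = _transport_frames(pts)
    theta = np.linspace(0.0, 2.0 * np.pi, sections, endpoint=False)
    ring = np.cos(theta)[:, None, None] * normals[None] + np.sin(theta)[:, None, None] * binormals[None]
    verts = pts[None] + radius * ring  # (sections, n, 3)
    verts = verts.transpose(1, 0, 2).reshape(-1, 3)  # ring-major per station

    n = pts.shape[0]
    faces = []
    for i in range(n - 1):
        base0 = i * sections
        base1 = (i + 1) * sections
        j = np.arange(sections)
        jn = (j + 1) % sections
        quads0 = np.stack([base0 + j, base1 + j, base1 + jn], axis=1)
        quads1 = np.stack([base0 + j, base1 + jn, base0 + jn], axis=1)
        faces.append(quads0)
        faces.append(quads1)
    faces = np.concatenate(faces, axis=0)

    # end caps: fan to the station centerpoints
    verts = np.vstack([verts, pts[0], pts[-1]])
    c0 = len(verts) - 2
    c1 = len(verts) - 1
    j = np.arange(sections)
    jn = (j + 1) % sections
    cap0 = np.stack([np.full(sections, c0), jn, j], axis=1)
    last = (n - 1) * sections
    cap1 = np.stack([np.full(sections, c1), last + j, last + jn], axis=1)
    faces = np.vstack([faces, cap0, cap1])

    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if not mesh.is_watertight:  # pragma: no cover - construction guarantee
        raise RuntimeError("tube mesh construction produced a non-watertight mesh")
    if mesh.volume < 0:
        mesh.invert()
    return mesh
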