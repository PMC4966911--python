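"""Analytic integral kernels for the boundary element method.

Everything here works on raw coordinate arrays (SI metres) and is shared by the
solver, the head-model validators and the magnetics module.  The central
quantities are

* the signed solid angle of a triangle at a field point (van Oosterom &
  Strackee closed form), and
* the analytically integrated double-layer potential of the three linear (hat)
  basis functions on a triangle (de Munck's closed form), which reduces to the
  solid angle under the partition of unity.

Sign convention: solid angles are positive as seen from the *inside* of a
closed, outward-oriented surface, i.e. they sum to +4*pi at interior points
and to 0 at exterior points.
"""

from __future__ import annotations

import numpy as np

FOUR_PI = 4.0 * np.pi

# relative threshold below which a point counts as lying in the plane of a
# triangle (principal value -> 0 contribution)
_IN_PLANE = np.pi / 1e6


def _dot(a, b):
    return np.einsum("...i,...i->...", a, b)


def triangle_frames(tri_xyz: np.ndarray):
    """Unit normals and areas for (F, 3, 3) triangle corner arrays."""
    cr = np.cross(tri_xyz[:, 1] - tri_xyz[:, 0], tri_xyz[:, 2] - tri_xyz[:, 0])
    n2 = np.linalg.norm(cr, axis=1)
    areas = 0.5 * n2
    normals = cr / np.where(n2 > 0, n2, 1.0)[:, None]
    return normals, areas


def solid_angles(points: np.ndarray, tri_xyz: np.ndarray) -> np.ndarray:
    """Signed solid angle (steradians) of each triangle at each point.

    Parameters
    ----------
    points : (P, 3)
    tri_xyz : (F, 3, 3)

    Returns
    -------
    (P, F) array; rows sum to ~4*pi for interior points of a closed
    outward-oriented surface and ~0 for exterior points.
    """
    y1 = tri_xyz[None, :, 0, :] - points[:, None, :]
    y2 = tri_xyz[None, :, 1, :] - points[:, None, :]
    y3 = tri_xyz[None, :, 2, :] - points[:, None, :]
    l1 = np.linalg.norm(y1, axis=-1)
    l2 = np.linalg.norm(y2, axis=-1)
    l3 = np.linalg.norm(y3, axis=-1)
    triple = _dot(y1, np.cross(y2, y3))
    ss = l1 * l2 * l3 + _dot(y1, y2) * l3 + _dot(y1, y3) * l2 + _dot(y2, y3) * l1
    return 2.0 * np.arctan2(triple, ss)



def _in_plane_mask(y1, l1, l2, l3, normals, half_omega):
    """Points lying in the plane of a triangle: the principal value of the
    double layer vanishes there.  Detected by the signed plane distance
    relative to the corner-distance scale (catches points *on* the triangle,
    where the raw arctan branch would report +-2*pi instead of the PV 0)."""
    h = np.abs(_dot(y1, normals if normals.ndim == y1.ndim else normals[None]))
    scale = l1 + l2 + l3
    return (h <= 1e-12 * scale) | (np.abs(half_omega) < _IN_PLANE)

def _beta(ya, la, yb, lb):
    """Edge coefficient ln / length used in the linear-basis closed form."""
    d = yb - ya
    size = np.linalg.norm(d, axis=-1)
    size_safe = np.where(size > 0, size, 1.0)
    e = d / size_safe[..., None]
    num = la + _dot(ya, e)
    den = lb + _dot(yb, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(num / den) / size_safe
    return np.where((num > 0) & (den > 0) & (size > 0), out, 0.0)


def linear_basis_solid_angles(points: np.ndarray, tri_xyz: np.ndarray) -> np.ndarray:
    """Double-layer potential of the linear hat functions, analytically.

    Returns ``(P, F, 3)`` weights ``w[p, f, k] = int_T h_k(r') dOmega_p(r')``
    with the same sign convention as :func:`solid_angles`; for every triangle
    the three weights sum to its solid angle (partition of unity).  Points in
    the plane of a triangle get exactly zero for that triangle (the principal
    value of the double layer vanishes there).
    """
    normals, areas = triangle_frames(tri_xyz)
    y1 = tri_xyz[None, :, 0, :] - points[:, None, :]
    y2 = tri_xyz[None, :, 1, :] - points[:, None, :]
    y3 = tri_xyz[None, :, 2, :] - points[:, None, :]
    l1 = np.linalg.norm(y1, axis=-1)
    l2 = np.linalg.norm(y2, axis=-1)
    l3 = np.linalg.norm(y3, axis=-1)
    triple = _dot(y1, np.cross(y2, y3))
    ss = l1 * l2 * l3 + _dot(y1, y2) * l3 + _dot(y1, y3) * l2 + _dot(y2, y3) * l1
    half_omega = np.arctan2(triple, ss)
    bad = _in_plane_mask(y1, l1, l2, l3, normals, half_omega)

    b12 = _beta(y1, l1, y2, l2)
    b23 = _beta(y2, l2, y3, l3)
    b31 = _beta(y3, l3, y1, l1)
    vec = ((b31 - b12)[..., None] * y1
           + (b12 - b23)[..., None] * y2
           + (b23 - b31)[..., None] * y3)

    area2 = 2.0 * areas
    inv4a2 = 1.0 / np.where(area2 > 0, area2 * area2, 1.0)
    ys = (y1, y2, y3)
    out = np.empty(half_omega.shape + (3,))
    for k in range(3):
        y_next = ys[(k + 1) % 3]
        y_prev = ys[(k + 2) % 3]
        zdot = _dot(np.cross(y_next, y_prev), normals[None, :, :])
        diff = y_prev - y_next
        out[..., k] = inv4a2 * (area2 * zdot * 2.0 * half_omega
                                - triple * _dot(diff, vec))
    out[bad] = 0.0
    return out


def linear_basis_solid_angles_pairs(points: np.ndarray, tri_xyz: np.ndarray) -> np.ndarray:
    """Element-wise variant of :func:`linear_basis_solid_angles`: point ``i``
    against triangle ``i``.  points (N, 3), tri_xyz (N, 3, 3) -> (N, 3)."""
    normals, areas = triangle_frames(tri_xyz)
    y1 = tri_xyz[:, 0, :] - points
    y2 = tri_xyz[:, 1, :] - points
    y3 = tri_xyz[:, 2, :] - points
    l1 = np.linalg.norm(y1, axis=-1)
    l2 = np.linalg.norm(y2, axis=-1)
    l3 = np.linalg.norm(y3, axis=-1)
    triple = _dot(y1, np.cross(y2, y3))
    ss = l1 * l2 * l3 + _dot(y1, y2) * l3 + _dot(y1, y3) * l2 + _dot(y2, y3) * l1
    half_omega = np.arctan2(triple, ss)
    bad = _in_plane_mask(y1, l1, l2, l3, normals, half_omega)
    b12 = _beta(y1, l1, y2, l2)
    b23 = _beta(y2, l2, y3, l3)
    b31 = _beta(y3, l3, y1, l1)
    vec = ((b31 - b12)[..., None] * y1
           + (b12 - b23)[..., None] * y2
           + (b23 - b31)[..., None] * y3)
    area2 = 2.0 * areas
    inv4a2 = 1.0 / np.where(area2 > 0, area2 * area2, 1.0)
    ys = (y1, y2, y3)
    out = np.empty(points.shape[:1] + (3,))
    for k in range(3):
        y_next = ys[(k + 1) % 3]
        y_prev = ys[(k + 2) % 3]
        zdot = _dot(np.cross(y_next, y_prev), normals)
        diff = y_prev - y_next
        out[..., k] = inv4a2 * (area2 * zdot * 2.0 * half_omega - triple * _dot(diff, vec))
    out[bad] = 0.0
    return out


def closest_point_on_triangles(points: np.ndarray, tri_xyz: np.ndarray):
    """Closest point on any of the triangles for each query point.

    Vectorized Ericson-style clamped-barycentric projection.  Returns
    ``(closest (P, 3), distance (P,), face_index (P,), bary (P, 3))``.
    """
    points = np.atleast_2d(points)
    a = tri_xyz[None, :, 0, :]
    b = tri_xyz[None, :, 1, :]
    c = tri_xyz[None, :, 2, :]
    p = points[:, None, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = _dot(ab, ap)
    d2 = _dot(ac, ap)
    bp = p - b
    d3 = _dot(ab, bp)
    d4 = _dot(ac, bp)
    cp = p - c
    d5 = _dot(ab, cp)
    d6 = _dot(ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = vb / np.where(denom != 0, denom, 1.0)
    w = vc / np.where(denom != 0, denom, 1.0)

    # interior case
    u_int = 1.0 - v - w
    bary = np.stack([u_int, v, w], axis=-1)

    # edge/vertex regions: clamp
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0.0, 1.0)
        t_ac = np.clip(d2 / (d2 - d6), 0.0, 1.0)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0, 1.0)
    t_ab = np.nan_to_num(t_ab)
    t_ac = np.nan_to_num(t_ac)
    t_bc = np.nan_to_num(t_bc)

    region_a = (d1 <= 0) & (d2 <= 0)
    region_b = (d3 >= 0) & (d4 <= d3)
    region_c = (d6 >= 0) & (d5 <= d6)
    region_ab = (~region_a) & (~region_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    region_ac = (~region_a) & (~region_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    region_bc = (~region_b) & (~region_c) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    bary = np.where(region_bc[..., None],
                    np.stack([np.zeros_like(t_bc), 1 - t_bc, t_bc], -1), bary)
    bary = np.where(region_ac[..., None],
                    np.stack([1 - t_ac, np.zeros_like(t_ac), t_ac], -1), bary)
    bary = np.where(region_ab[..., None],
                    np.stack([1 - t_ab, t_ab, np.zeros_like(t_ab)], -1), bary)
    bary = np.where(region_c[..., None],
                    np.tile(np.array([0.0, 0.0, 1.0]), bary.shape[:-1] + (1,)), bary)
    bary = np.where(region_b[..., None],
                    np.tile(np.array([0.0, 1.0, 0.0]), bary.shape[:-1] + (1,)), bary)
    bary = np.where(region_a[..., None],
                    np.tile(np.array([1.0, 0.0, 0.0]), bary.shape[:-1] + (1,)), bary)

    closest = bary[..., 0:1] * a + bary[..., 1:2] * b + bary[..., 2:3] * c
    dists = np.linalg.norm(closest - p, axis=-1)
    idx = np.argmin(dists, axis=1)
    rows = np.arange(len(points))
    return closest[rows, idx], dists[rows, idx], idx, bary[rows, idx]


def edge_inverse_distance_integrals(points: np.ndarray, va: np.ndarray,
                                    vb: np.ndarray) -> np.ndarray:
    """``int_a^b dl' / |r - r'|`` along straight edges, closed form.

    points: (P, 3); va, vb: (E, 3).  Returns (P, E).
    """
    d = vb - va
    size = np.linalg.norm(d, axis=-1)
    e = d / np.where(size > 0, size, 1.0)[:, None]
    ya = va[None, :, :] - points[:, None, :]
    yb = vb[None, :, :] - points[:, None, :]
    la = np.linalg.norm(ya, axis=-1)
    lb = np.linalg.norm(yb, axis=-1)
    num = lb + _dot(yb, e[None])
    den = la + _dot(ya, e[None])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(num / den)
    return np.where((num > 0) & (den > 0), out, 0.0)


# ----------------------------------------------------------------------------
# Triangle quadrature (barycentric rules on the unit triangle)
# ----------------------------------------------------------------------------

def triangle_rule(order: int):
    """Symmetric barycentric quadrature rules: (nodes (Q, 3), weights (Q,)).

    ``order`` 3 is the degree-2 interior-point rule; 7 is the degree-5 Radon
    rule.  Weights sum to 1 (multiply by the triangle area to integrate).
    """
    if order == 1:
        return np.array([[1 / 3, 1 / 3, 1 / 3]]), np.array([1.0])
    if order == 3:
        pts = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
        return pts, np.full(3, 1 / 3)
    if order == 7:
        a = (6.0 + np.sqrt(15.0)) / 21.0
        b = (6.0 - np.sqrt(15.0)) / 21.0
        wa = (155.0 + np.sqrt(15.0)) / 1200.0
        wb = (155.0 - np.sqrt(15.0)) / 1200.0
        pts = [[1 / 3, 1 / 3, 1 / 3]]
        wts = [9.0 / 40.0]
        for (c, w) in ((a, wa), (b, wb)):
            pts += [[1 - 2 * c, c, c], [c, 1 - 2 * c, c], [c, c, 1 - 2 * c]]
            wts += [w, w, w]
        return np.array(pts), np.array(wts)
    raise ValueError(f"no rule with {order} points")


def refined_rule(order: int, depth: int):
    """Quadrature rule composed on ``4**depth`` congruent sub-triangles.

    Used for outer Galerkin integrals of near-singular (edge/vertex-adjacent)
    triangle pairs, where a single rule on the whole triangle is too coarse.
    """
    pts, wts = triangle_rule(order)
    corners = np.eye(3)
    tris = [corners]
    for _ in range(depth):
        nxt = []
        for t in tris:
            m01 = 0.5 * (t[0] + t[1])
            m12 = 0.5 * (t[1] + t[2])
            m20 = 0.5 * (t[2] + t[0])
            nxt += [np.array([t[0], m01, m20]), np.array([m01, t[1], m12]),
                    np.array([m20, m12, t[2]]), np.array([m01, m12, m20])]
        tris = nxt
    all_pts = np.concatenate([pts @ t for t in tris], axis=0)
    all_wts = np.tile(wts / len(tris), len(tris))
    return all_pts, all_wts
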