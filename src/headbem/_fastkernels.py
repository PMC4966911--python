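"""Numba-compiled assembly loops for the BEM double-layer matrices.

These are exact scalar re-implementations of the closed forms in
:mod:`headbem._kernels`, arranged as accumulation loops so that the large
(point x face) weight tensors never materialize.  The numpy kernels remain
the reference implementation; agreement between the two is covered by tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["lc_weight_rows", "galerkin_block_accumulate"]


@njit(cache=True, inline="always")
def _tri_weights(px, py, pz, t, f):
    """Linear-basis double-layer weights of triangle ``f`` of corner array
    ``t`` (F, 3, 3) at point (px, py, pz); returns (w0, w1, w2)."""
    y1x = t[f, 0, 0] - px
    y1y = t[f, 0, 1] - py
    y1z = t[f, 0, 2] - pz
    y2x = t[f, 1, 0] - px
    y2y = t[f, 1, 1] - py
    y2z = t[f, 1, 2] - pz
    y3x = t[f, 2, 0] - px
    y3y = t[f, 2, 1] - py
    y3z = t[f, 2, 2] - pz
    l1 = np.sqrt(y1x * y1x + y1y * y1y + y1z * y1z)
    l2 = np.sqrt(y2x * y2x + y2y * y2y + y2z * y2z)
    l3 = np.sqrt(y3x * y3x + y3y * y3y + y3z * y3z)
    # triangle frame (normal * 2A)
    ux = t[f, 1, 0] - t[f, 0, 0]
    uy = t[f, 1, 1] - t[f, 0, 1]
    uz = t[f, 1, 2] - t[f, 0, 2]
    vx = t[f, 2, 0] - t[f, 0, 0]
    vy = t[f, 2, 1] - t[f, 0, 1]
    vz = t[f, 2, 2] - t[f, 0, 2]
    cnx = uy * vz - uz * vy
    cny = uz * vx - ux * vz
    cnz = ux * vy - uy * vx
    n2 = np.sqrt(cnx * cnx + cny * cny + cnz * cnz)
    if n2 <= 0.0:
        return 0.0, 0.0, 0.0
    nx = cnx / n2
    ny = cny / n2
    nz = cnz / n2
    area2 = n2

    c23x = y2y * y3z - y2z * y3y
    c23y = y2z * y3x - y2x * y3z
    c23z = y2x * y3y - y2y * y3x
    triple = y1x * c23x + y1y * c23y + y1z * c23z
    ss = (l1 * l2 * l3
          + (y1x * y2x + y1y * y2y + y1z * y2z) * l3
          + (y1x * y3x + y1y * y3y + y1z * y3z) * l2
          + (y2x * y3x + y2y * y3y + y2z * y3z) * l1)
    half_omega = np.arctan2(triple, ss)

    # in-plane principal value -> 0
    h = abs(y1x * nx + y1y * ny + y1z * nz)
    if h <= 1e-12 * (l1 + l2 + l3) or abs(half_omega) < np.pi / 1e6:
        return 0.0, 0.0, 0.0

    # edge log coefficients
    b12 = _beta_s(y1x, y1y, y1z, l1, y2x, y2y, y2z, l2)
    b23 = _beta_s(y2x, y2y, y2z, l2, y3x, y3y, y3z, l3)
    b31 = _beta_s(y3x, y3y, y3z, l3, y1x, y1y, y1z, l1)
    vx_ = (b31 - b12) * y1x + (b12 - b23) * y2x + (b23 - b31) * y3x
    vy_ = (b31 - b12) * y1y + (b12 - b23) * y2y + (b23 - b31) * y3y
    vz_ = (b31 - b12) * y1z + (b12 - b23) * y2z + (b23 - b31) * y3z

    inv4a2 = 1.0 / (area2 * area2)
    # k = 0: zdot = (y2 x y3).n, diff = y3 - y2
    z0 = c23x * nx + c23y * ny + c23z * nz
    d0 = (y3x - y2x) * vx_ + (y3y - y2y) * vy_ + (y3z - y2z) * vz_
    w0 = inv4a2 * (area2 * z0 * 2.0 * half_omega - triple * d0)
    # k = 1: zdot = (y3 x y1).n, diff = y1 - y3
    c31x = y3y * y1z - y3z * y1y
    c31y = y3z * y1x - y3x * y1z
    c31z = y3x * y1y - y3y * y1x
    z1 = c31x * nx + c31y * ny + c31z * nz
    d1 = (y1x - y3x) * vx_ + (y1y - y3y) * vy_ + (y1z - y3z) * vz_
    w1 = inv4a2 * (area2 * z1 * 2.0 * half_omega - triple * d1)
    # k = 2: zdot = (y1 x y2).n, diff = y2 - y1
    c12x = y1y * y2z - y1z * y2y
    c12y = y1z * y2x - y1x * y2z
    c12z = y1x * y2y - y1y * y2x
    z2 = c12x * nx + c12y * ny + c12z * nz
    d2 = (y2x - y1x) * vx_ + (y2y - y1y) * vy_ + (y2z - y1z) * vz_
    w2 = inv4a2 * (area2 * z2 * 2.0 * half_omega - triple * d2)
    return w0, w1, w2


@njit(cache=True, inline="always")
def _beta_s(ax, ay, az, la, bx, by, bz, lb):
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    size = np.sqrt(dx * dx + dy * dy + dz * dz)
    if size <= 0.0:
        return 0.0
    ex = dx / size
    ey = dy / size
    ez = dz / size
    num = la + ax * ex + ay * ey + az * ez
    den = lb + bx * ex + by * ey + bz * ez
    if num <= 0.0 or den <= 0.0:
        return 0.0
    return np.log(num / den) / size


@njit(cache=True)
def lc_weight_rows(points, tri, faces, n_verts):
    """Dense (P x V) double-layer weight rows by direct accumulation."""
    n_p = points.shape[0]
    n_f = tri.shape[0]
    out = np.zeros((n_p, n_verts))
    for p in range(n_p):
        px = points[p, 0]
        py = points[p, 1]
        pz = points[p, 2]
        for f in range(n_f):
            w0, w1, w2 = _tri_weights(px, py, pz, tri, f)
            out[p, faces[f, 0]] += w0
            out[p, faces[f, 1]] += w1
            out[p, faces[f, 2]] += w2
    return out


@njit(cache=True)
def galerkin_block_accumulate(qpts, qface, qbary, qwa, outer_faces, tri, faces, out):
    """Accumulate Galerkin rows: for each outer quadrature point q belonging
    to ``outer_faces[qface[q]]`` with hat values ``qbary[q]`` and weight
    ``qwa[q]``, add the weighted inner analytic rows over the basis surface
    (``tri``/``faces``) into ``out`` (V_outer x V_basis)."""
    n_q = qpts.shape[0]
    n_f = tri.shape[0]
    for q in range(n_q):
        px = qpts[q, 0]
        py = qpts[q, 1]
        pz = qpts[q, 2]
        fo = qface[q]
        r0 = outer_faces[fo, 0]
        r1 = outer_faces[fo, 1]
        r2 = outer_faces[fo, 2]
        h0 = qbary[q, 0] * qwa[q]
        h1 = qbary[q, 1] * qwa[q]
        h2 = qbary[q, 2] * qwa[q]
        for f in range(n_f):
            w0, w1, w2 = _tri_weights(px, py, pz, tri, f)
            if w0 == 0.0 and w1 == 0.0 and w2 == 0.0:
                continue
            c0 = faces[f, 0]
            c1 = faces[f, 1]
            c2 = faces[f, 2]
            out[r0, c0] += h0 * w0
            out[r0, c1] += h0 * w1
            out[r0, c2] += h0 * w2
            out[r1, c0] += h1 * w0
            out[r1, c1] += h1 * w1
            out[r1, c2] += h1 * w2
            out[r2, c0] += h2 * w0
            out[r2, c1] += h2 * w1
            out[r2, c2] += h2 * w2
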