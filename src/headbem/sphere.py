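"""Analytic reference solutions for spherically symmetric conductors.

Two classical results serve as ground truth for solver verification:

* the spherical-harmonic series for the potential of a current dipole inside
  a piecewise-constant layered (concentric-sphere) conductor, with the
  boundary conditions of continuous potential and continuous normal current
  applied layer by layer; and
* the Sarvas closed form for the magnetic field outside *any* spherically
  symmetric conductor, which depends on the dipole and geometry only (the
  conductivity profile drops out entirely).

The series is evaluated in radii scaled by the outer radius, which keeps the
per-degree transfer systems well conditioned up to the truncation orders
needed for eccentric sources; truncation is adaptive until the partial sums
stabilize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sources import MU0

__all__ = ["LayeredSphereSpec", "multilayer_sphere_potential", "sarvas_field", "MU0"]


@dataclass(frozen=True)
class LayeredSphereSpec:
    """Concentric conductor layers: ``radii_m`` strictly ascending outer radii
    and ``conductivities`` (S/m) of the corresponding layers, innermost
    first; outside the last radius is non-conducting."""

    radii_m: tuple
    conductivities: tuple
    center_m: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        r = tuple(float(x) for x in self.radii_m)
        c = tuple(float(x) for x in self.conductivities)
        if len(r) != len(c):
            raise ValueError("need one conductivity per layer")
        if any(b <= a for a, b in zip(r, r[1:])):
            raise ValueError(f"radii must be strictly ascending, got {r}")
        if any(s <= 0 for s in c):
            raise ValueError("layer conductivities must be positive")
        object.__setattr__(self, "radii_m", r)
        object.__setattr__(self, "conductivities", c)

    @classmethod
    def from_head_model(cls, model) -> "LayeredSphereSpec":
        """Spec matching a concentric layered-sphere head model (uses each
        surface's mean vertex radius and its inner conductivity)."""
        radii, sig = [], []
        c = np.zeros(3)
        for s in model.surfaces:
            v = s.mesh.vertices_m
            radii.append(float(np.linalg.norm(v - v.mean(0), axis=1).mean()))
            sig.append(s.sigma_in)
            c = v.mean(0)
        return cls(tuple(radii), tuple(sig), tuple(c))


def _transfer_solve(n: int, xb: np.ndarray, sig: np.ndarray, c_src: float) -> np.ndarray:
    """Per-degree layer coefficients [A_1, A_2, B_2, ..., A_L, B_L] for a
    source term c_src * x^-(n+1) in the innermost layer (scaled radii)."""
    n_lay = len(sig)
    m = 2 * n_lay - 1
    a_mat = np.zeros((m, m))
    rhs = np.zeros(m)

    def col_a(j):  # index of A_j
        return 0 if j == 0 else 2 * j - 1

    def col_b(j):  # index of B_j, j >= 1
        return 2 * j

    for j in range(n_lay - 1):  # interface at xb[j] between layer j and j+1
        x = xb[j]
        xn = x ** n
        xm = x ** (-(n + 1))
        row_c = 2 * j
        row_f = 2 * j + 1
        # continuity of potential
        a_mat[row_c, col_a(j)] += xn
        if j > 0:
            a_mat[row_c, col_b(j)] += xm
        a_mat[row_c, col_a(j + 1)] -= xn
        a_mat[row_c, col_b(j + 1)] -= xm
        if j == 0:
            rhs[row_c] -= c_src * xm
        # continuity of sigma * d/dr
        dn = n * x ** (n - 1)
        dm = -(n + 1) * x ** (-(n + 2))
        a_mat[row_f, col_a(j)] += sig[j] * dn
        if j > 0:
            a_mat[row_f, col_b(j)] += sig[j] * dm
        a_mat[row_f, col_a(j + 1)] -= sig[j + 1] * dn
        a_mat[row_f, col_b(j + 1)] -= sig[j + 1] * dm
        if j == 0:
            rhs[row_f] -= sig[0] * c_src * dm
    # outer boundary: no radial current at x = 1
    row = m - 1
    a_mat[row, col_a(n_lay - 1)] += n
    if n_lay > 1:
        a_mat[row, col_b(n_lay - 1)] += -(n + 1)
        rhs[row] += 0.0
    else:
        rhs[row] -= c_src * (-(n + 1))
    if n_lay == 1:
        # single layer: only A_1 unknown, equation sigma*(n A_1 - (n+1) c) = 0
        return np.array([c_src * (n + 1) / n])
    return np.linalg.solve(a_mat, rhs)


def multilayer_sphere_potential(spec: LayeredSphereSpec, dipole_position_m,
                                dipole_moment, points_m,
                                rtol: float = 1e-10, max_degree: int = 2000) -> np.ndarray:
    """Potential (V) of a current dipole in a layered sphere at given points.

    The dipole must lie strictly inside the innermost layer; evaluation
    points may lie in any layer (typically on or just inside the outer
    surface).  Truncation is adaptive: the series stops once three
    consecutive degree increments are below ``rtol`` of the accumulated sum.
    """
    center = np.asarray(spec.center_m, float)
    r0 = np.asarray(dipole_position_m, float) - center
    p = np.asarray(dipole_moment, float)
    pts = np.atleast_2d(np.asarray(points_m, float)) - center
    radii = np.asarray(spec.radii_m)
    sig = np.asarray(spec.conductivities)
    r_out = radii[-1]

    b = np.linalg.norm(r0)
    if b >= radii[0]:
        raise ValueError(f"dipole radius {b:.4g} m is not inside the innermost "
                         f"layer (radius {radii[0]:.4g} m)")
    # local frame: z along the dipole position (or moment, for a central dipole)
    if b > 1e-12 * r_out:
        ez = r0 / b
    else:
        nrm = np.linalg.norm(p)
        ez = p / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
    p_r = float(p @ ez)
    p_tan = p - p_r * ez
    p_t = float(np.linalg.norm(p_tan))
    ex = p_tan / p_t if p_t > 1e-300 else _any_perpendicular(ez)
    ey = np.cross(ez, ex)

    # scaled coordinates
    xb = radii / r_out
    b_s = b / r_out
    r_pts = np.linalg.norm(pts, axis=1)
    x_pts = r_pts / r_out
    if np.any(x_pts > 1.0 + 1e-9):
        raise ValueError("evaluation points must lie inside the conductor")
    if np.any(r_pts <= b):
        raise ValueError("evaluation points must lie outside the dipole radius")
    layer_idx = np.searchsorted(xb, x_pts * (1 - 1e-12))
    layer_idx = np.clip(layer_idx, 0, len(sig) - 1)

    cos_t = np.clip(pts @ ez / np.where(r_pts > 0, r_pts, 1.0), -1.0, 1.0)
    sin_t_cphi = pts @ ex / np.where(r_pts > 0, r_pts, 1.0)

    # Legendre recurrences: P_n(cos) and the Ferrers P_n^1(cos)/sin * sin*cos(phi)
    # handled as Q_n = P_n^1(cos_t) * cos(phi); note
    # P_n^1(x) = sin_t * dP_n/dx, so Q_n = sin_t_cphi * dP_n/dx(cos_t).
    phi = np.zeros(len(pts))
    p_nm1 = np.ones_like(cos_t)      # P_0
    p_n = cos_t.copy()               # P_1
    dp_nm1 = np.zeros_like(cos_t)    # P_0'
    dp_n = np.ones_like(cos_t)       # P_1'
    quiet = 0
    scale = 1.0 / (4.0 * np.pi * sig[0] * r_out ** 2)
    for n in range(1, max_degree + 1):
        if n > 1:
            p_n, p_nm1 = ((2 * n - 1) * cos_t * p_n - (n - 1) * p_nm1) / n, p_n
            dp_n, dp_nm1 = ((2 * n - 1) * (p_nm1 + cos_t * dp_n) - (n - 1) * dp_nm1) / n, dp_n
        b_pow = b_s ** (n - 1)
        if b_pow == 0.0:
            return phi  # central dipole: only the n = 1 term exists
        inc = np.zeros(len(pts))
        for c_src, ang in ((p_r * n * b_pow, p_n),
                           (p_t * b_pow, sin_t_cphi * dp_n)):
            if c_src == 0.0:
                continue
            coefs = _transfer_solve(n, xb, sig, c_src)
            a_all = np.concatenate([[coefs[0]], coefs[1::2]]) if len(sig) > 1 else coefs[:1]
            b_all = np.concatenate([[c_src], coefs[2::2]]) if len(sig) > 1 else np.array([c_src])
            # B of layer 1 is the source coefficient itself
            a_pt = a_all[layer_idx]
            b_pt = b_all[layer_idx]
            rad = a_pt * x_pts ** n + b_pt * x_pts ** (-(n + 1))
            inc += rad * ang
        phi_inc = scale * inc
        phi += phi_inc
        ref = np.linalg.norm(phi)
        if ref > 0 and np.linalg.norm(phi_inc) < rtol * ref:
            quiet += 1
            if quiet >= 3:
                return phi
        else:
            quiet = 0
    raise RuntimeError(f"series did not converge within {max_degree} degrees "
                       f"(dipole eccentricity {b / radii[0]:.3f})")


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    out = np.cross(v, w)
    return out / np.linalg.norm(out)


def sarvas_field(dipole_position_m, dipole_moment, points_m,
                 sphere_center_m=(0.0, 0.0, 0.0)) -> np.ndarray:
    """External magnetic field (T) of a dipole in a spherically symmetric
    conductor (Sarvas closed form); (P, 3) vectors.

    Independent of the conductivity profile.  Raises on the singular
    configuration where the field point lies on the dipole ray through the
    center (F -> 0) — physically, on such a ray the formula's scalar
    potential parameterization breaks down.
    """
    c = np.asarray(sphere_center_m, float)
    r0 = np.asarray(dipole_position_m, float) - c
    q = np.asarray(dipole_moment, float)
    r = np.atleast_2d(np.asarray(points_m, float)) - c

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    r_n = np.linalg.norm(r, axis=1)
    if np.any(r_n <= np.linalg.norm(r0)):
        raise ValueError("field points must lie outside the sphere containing the dipole")
    f = a * (r_n * a + r_n ** 2 - r @ r0)
    if np.any(np.abs(f) < 1e-300):
        raise ValueError("field point on the singular dipole ray (F = 0)")
    adot = np.einsum("ij,ij->i", a_vec, r)
    grad_f = ((a ** 2 / r_n + adot / a + 2 * a + 2 * r_n)[:, None] * r
              - (a + 2 * r_n + adot / a)[:, None] * r0[None, :])
    qxr0 = np.cross(q, r0)
    return MU0 / (4 * np.pi * f ** 2)[:, None] * (f[:, None] * qxr0[None, :]
                                                  - (r @ qxr0)[:, None] * grad_f)
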