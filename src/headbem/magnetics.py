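"""Magnetic fields of volume currents (Geselowitz equation) and EEG/MEG
leadfield computation.

Outside the conductor the magnetic field is the primary (infinite-medium)
dipole field plus a volume-current term that depends only on the boundary
potentials and the conductivity jumps:

    B(r) = B_inf(r)
           - (mu0 / 4 pi) * sum_l (sigma_in_l - sigma_out_l)
             * int_{S_l} phi(r') dS'(r') x (r - r') / |r - r'|^3

(the sign follows from writing the volume currents as curls of phi *
grad(1/R) per homogeneous compartment and applying the curl theorem).

With linear potential on each triangle the integral is split into the
triangle-mean part — integrated *exactly* through the Stokes identity
``int_T n x grad'(1/R) dS' = closed line integral of (1/R) dl`` with
closed-form edge integrals, so closed-surface identities (constant potential
contributes nothing; zero-jump surfaces are inert) hold to rounding — and a
zero-mean linear residual handled by a 3-point triangle rule.

Leadfields are assembled channel-side: a sensor weight matrix is pushed
through the adjoint BEM solve once, after which any number of sources costs
one matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels, bem
from .headmodel import HeadModel
from .sources import (MU0, ElectrodeArray, MagnetometerArray, SourceSpace,
                      dipole_primary_field)

__all__ = [
    "MU0",
    "Leadfield",
    "geselowitz_volume_field",
    "eeg_leadfield",
    "meg_leadfield",
]


@dataclass(frozen=True)
class Leadfield:
    """Channels x sources topography matrix with its provenance."""

    matrix: np.ndarray
    modality: str  # "EEG" | "MEG"
    channel_names: tuple = ()
    source_space: SourceSpace | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2:
            raise ValueError("leadfield matrix must be 2-D (channels x sources)")
        if not np.all(np.isfinite(m)):
            raise ValueError("leadfield contains non-finite entries")
        object.__setattr__(self, "matrix", m)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# Geselowitz volume-current term
# ---------------------------------------------------------------------------

def _volume_rows(mesh, field_points_m: np.ndarray, quad_order: int = 3) -> np.ndarray:
    """Unscaled volume-current weight rows: (P, 3, V) mapping nodal potentials
    on ``mesh`` to the surface integral ``int phi dS' x (r-r')/R^3``."""
    pts = field_points_m
    verts = mesh.vertices_m
    faces = mesh.faces
    tri = verts[faces]
    normals, areas = _kernels.triangle_frames(tri)
    n_p, n_v = len(pts), mesh.n_vertices
    out = np.zeros((n_p, 3, n_v))

    # exact triangle-mean part via the Stokes edge identity
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    e_a = verts[uniq[:, 0]]
    e_b = verts[uniq[:, 1]]
    ints = _kernels.edge_inverse_distance_integrals(pts, e_a, e_b)  # (P, E)
    dirs = e_b - e_a
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    # directed sign of each face edge w.r.t. the canonical unique edge
    sign = np.where(edges[:, 0] == uniq[inv, 0], 1.0, -1.0)  # (3F,)
    # C_f(r) = sum_k sign * dir * I_e ; distribute C_f/3 to the face vertices
    for k in range(3):
        cols = faces[:, k]
        for e_slot in range(3):
            rows_e = inv[e_slot * len(faces):(e_slot + 1) * len(faces)]
            s = sign[e_slot * len(faces):(e_slot + 1) * len(faces)]
            contrib = ints[:, rows_e][:, None, :] * (s[None, :] * dirs[rows_e].T[None])  # (P,3,F)
            np.add.at(out, (slice(None), slice(None), cols), contrib / 3.0)

    # zero-mean linear residual by quadrature
    bary, wts = _kernels.triangle_rule(quad_order)
    qpts = np.einsum("qb,fbx->fqx", bary, tri)  # (F, Q, 3)
    y = pts[:, None, None, :] - qpts[None, :, :, :]  # (P, F, Q, 3)
    r3 = np.linalg.norm(y, axis=-1) ** 3
    kern = np.cross(np.broadcast_to(normals[None, :, None, :], y.shape), y) / r3[..., None]
    for k in range(3):
        res = bary[:, k] - 1.0 / 3.0  # zero-mean hat residual at quad nodes
        w_eff = wts * res  # (Q,)
        contrib = np.einsum("pfqx,q,f->pxf", kern, w_eff, areas)
        np.add.at(out, (slice(None), slice(None), faces[:, k]), contrib)
    return out


def geselowitz_volume_field(model: HeadModel, nodal_potentials: np.ndarray,
                            field_points_m, quad_order: int = 3,
                            check_outside: bool = True) -> np.ndarray:
    """Volume-current magnetic field (T) at exterior points: (P, 3, S).

    ``nodal_potentials`` stacks the per-surface boundary potentials in model
    surface order (as returned by :func:`headbem.bem.solve_potentials`).
    """
    pts = np.atleast_2d(np.asarray(field_points_m, float))
    phi = np.asarray(nodal_potentials, float)
    if phi.ndim == 1:
        phi = phi[:, None]
    n_tot = sum(s.mesh.n_vertices for s in model.surfaces)
    if phi.shape[0] != n_tot:
        raise ValueError(f"expected {n_tot} nodal potentials, got {phi.shape[0]}")
    if check_outside:
        outer = model.surfaces[int(np.argmax([abs(s.mesh.signed_volume())
                                              for s in model.surfaces]))]
        wind = _kernels.solid_angles(pts * 1000.0, outer.mesh.triangles).sum(1) / _kernels.FOUR_PI
        if np.any(wind > 0.5):
            raise ValueError("field points must lie outside the conductor")
    out = np.zeros((len(pts), 3, phi.shape[1]))
    off = 0
    for s in model.surfaces:
        nv = s.mesh.n_vertices
        if s.jump != 0.0:
            rows = _volume_rows(s.mesh, pts, quad_order)
            out -= s.jump * np.einsum("pxv,vs->pxs", rows, phi[off:off + nv])
        off += nv
    return MU0 / (4.0 * np.pi) * out


def _meg_volume_weights(model: HeadModel, magnetometers: MagnetometerArray,
                        quad_order: int = 3) -> np.ndarray:
    """(C x N) matrix mapping nodal potentials to coil readings of the
    volume-current field."""
    ipts = magnetometers.integration_points_m.reshape(-1, 3)
    n_tot = sum(s.mesh.n_vertices for s in model.surfaces)
    out = np.zeros((len(magnetometers), n_tot))
    off = 0
    for s in model.surfaces:
        nv = s.mesh.n_vertices
        if s.jump != 0.0:
            rows = _volume_rows(s.mesh, ipts, quad_order)  # (C*4, 3, V)
            rows = rows.reshape(len(magnetometers), 4, 3, nv)
            w = np.einsum("cqxv,cx,q->cv", rows, magnetometers.normals,
                          magnetometers.weights)
            out[:, off:off + nv] = -s.jump * w
        off += nv
    return MU0 / (4.0 * np.pi) * out


# ---------------------------------------------------------------------------
# leadfields
# ---------------------------------------------------------------------------

def _scalp_block_offset(system: bem.BemSystem, mesh) -> int:
    for l, m in enumerate(system.geometry.meshes):
        if m is mesh or (m.n_vertices == mesh.n_vertices
                         and np.array_equal(m.vertices, mesh.vertices)):
            return int(system.geometry.offsets[l])
    raise ValueError("electrode mesh is not a surface of the BEM system")


def eeg_leadfield(model: HeadModel, system: bem.BemSystem, sources: SourceSpace,
                  electrodes: ElectrodeArray, average_reference: bool = True,
                  precomputed_terms: np.ndarray | None = None) -> Leadfield:
    """Average-referenced electrode potentials per source (channels x sources)."""
    w_scalp = electrodes.interpolation_matrix()
    w = np.zeros((len(electrodes), system.n))
    off = _scalp_block_offset(system, electrodes.mesh)
    w[:, off:off + electrodes.mesh.n_vertices] = w_scalp
    if average_reference:
        w -= w.mean(axis=0, keepdims=True)
    t = bem.transfer_matrix(system, w)
    terms = (precomputed_terms if precomputed_terms is not None
             else bem.source_terms(system, sources.positions_m, sources.moments))
    return Leadfield(t @ terms, "EEG", channel_names=electrodes.names,
                     source_space=sources,
                     info={"average_reference": average_reference,
                           "method": system.method, "isa": system.use_isa})


def meg_leadfield(model: HeadModel, system: bem.BemSystem, sources: SourceSpace,
                  magnetometers: MagnetometerArray, quad_order: int = 3,
                  precomputed_terms: np.ndarray | None = None) -> Leadfield:
    """Magnetometer readings (T) per source: primary + volume-current parts."""
    m_vol = _meg_volume_weights(model, magnetometers, quad_order)
    t = bem.transfer_matrix(system, m_vol)
    terms = (precomputed_terms if precomputed_terms is not None
             else bem.source_terms(system, sources.positions_m, sources.moments))
    vol = t @ terms

    ipts = magnetometers.integration_points_m  # (C, 4, 3)
    flat = ipts.reshape(-1, 3)
    prim = np.empty((len(magnetometers), len(sources)))
    for j in range(len(sources)):
        b = dipole_primary_field((sources.positions_m[j], sources.moments[j]), flat)
        b = b.reshape(len(magnetometers), 4, 3)
        prim[:, j] = np.einsum("cqx,cx,q->c", b, magnetometers.normals,
                               magnetometers.weights)
    return Leadfield(prim + vol, "MEG", channel_names=magnetometers.names,
                     source_space=sources,
                     info={"method": system.method, "isa": system.use_isa,
                           "quad_order": quad_order})
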