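"""Linear-basis boundary element solver for the EEG potential equation.

The electric potential of a piecewise-homogeneous conductor obeys, on each
boundary surface S_k,

    2*pi*(sigma_in + sigma_out) * phi(r)
        = 4*pi*sigma_0 * phi_inf(r)
          + sum_l (sigma_in_l - sigma_out_l) * PV int_{S_l} phi dOmega_r ,

where phi_inf is the infinite-medium potential of the primary current and
dOmega_r the solid-angle measure seen from r (positive from inside).  The
potential is discretized with linear (hat) basis functions on triangle
meshes; the residual is weighted either pointwise at vertices (linear
collocation, LC) or with the hat functions themselves (linear Galerkin, LG).
Double-layer integrals of the hat functions are evaluated with de Munck's
closed form; LG outer integrals use a degree-5 (7-point) triangle rule with
subdivision refinement for edge/vertex-adjacent triangle pairs.

Own-surface diagonal entries are closed so that constant potentials lie
exactly in the operator null space; that null space is then removed by a
rank-one deflation constraining the mean outer-surface potential to zero.

The isolated source approach (ISA) improves accuracy in the presence of the
poorly conducting skull: the sub-model inside and including the isolation
surface (inner skull by default) is solved first with zero outside
conductivity, and the full right-hand side is then rebuilt from this isolated
potential through the same discretized operators, cancelling analytically the
large source terms that otherwise amplify discretization error.

Geometry-dependent matrices are assembled once per (meshes, method) in
:class:`BemGeometry`; conductivities (e.g. a skull-ratio sweep) are applied
cheaply in :func:`assemble_system`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from . import _fastkernels, _kernels
from .geometry import TriMesh
from .headmodel import HeadModel

__all__ = [
    "BemGeometry",
    "BemSystem",
    "solid_angles",
    "linear_collocation_weights",
    "assemble_geometry",
    "assemble_system",
    "source_terms",
    "solve_potentials",
    "transfer_matrix",
]

# ---------------------------------------------------------------------------
# public kernel wrappers (mm interface, per the geometry module convention)
# ---------------------------------------------------------------------------

def _require_off_surface(points_mm: np.ndarray, mesh: TriMesh, tol_mm: float = 1e-6):
    _, d, _, _ = _kernels.closest_point_on_triangles(points_mm, mesh.triangles)
    if np.any(d < tol_mm):
        bad = int(np.argmin(d))
        raise ValueError(f"point {bad} lies on the surface (distance {d.min():.3g} mm); "
                         "the solid-angle kernel is singular there")


def solid_angles(mesh: TriMesh, points_mm) -> np.ndarray:
    """Signed solid angle (sr) of every face at every point (points x faces).

    Rows sum to 4*pi for interior and 0 for exterior points of a closed,
    outward-oriented mesh.  Points on the surface are rejected.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, float))
    _require_off_surface(points_mm, mesh)
    return _kernels.solid_angles(points_mm, mesh.triangles)


def linear_collocation_weights(mesh: TriMesh, points_mm, on_mesh: bool = False) -> np.ndarray:
    """Analytic double-layer weights of the hat basis: (points x vertices).

    Per triangle the three hat weights sum to the triangle's solid angle.
    With ``on_mesh`` the points are taken to be mesh vertices and the
    (vanishing) principal-value self-terms are kept at zero instead of
    rejecting the points.
    """
    points_mm = np.atleast_2d(np.asarray(points_mm, float))
    if not on_mesh:
        _require_off_surface(points_mm, mesh)
    w = _kernels.linear_basis_solid_angles(points_mm, mesh.triangles)
    scatter = _face_scatter(mesh)
    return w.reshape(len(points_mm), -1) @ scatter


def _face_scatter(mesh: TriMesh) -> sp.csr_matrix:
    """Sparse (3F x V) matrix summing per-face-corner weights into vertices."""
    f = mesh.faces
    rows = np.arange(3 * len(f))
    cols = f.reshape(-1)
    return sp.csr_matrix((np.ones(3 * len(f)), (rows, cols)),
                         shape=(3 * len(f), mesh.n_vertices))


# ---------------------------------------------------------------------------
# geometry-dependent assembly
# ---------------------------------------------------------------------------

def _weight_rows(points_m: np.ndarray, tri_m: np.ndarray, faces: np.ndarray,
                 n_verts: int) -> np.ndarray:
    """Dense (P x V) double-layer weight rows (compiled accumulation loop)."""
    return _fastkernels.lc_weight_rows(np.ascontiguousarray(points_m),
                                       np.ascontiguousarray(tri_m),
                                       np.ascontiguousarray(faces), n_verts)


def _mass_matrix(mesh_m_tri, faces, n_verts) -> sp.csr_matrix:
    """Linear FEM mass matrix of a triangle surface (exact)."""
    _, areas = _kernels.triangle_frames(mesh_m_tri)
    ii, jj, vv = [], [], []
    local = (np.ones((3, 3)) + np.eye(3)) / 12.0
    for a in range(3):
        for b in range(3):
            ii.append(faces[:, a])
            jj.append(faces[:, b])
            vv.append(areas * local[a, b])
    return sp.csr_matrix((np.concatenate(vv), (np.concatenate(ii), np.concatenate(jj))),
                         shape=(n_verts, n_verts))


def _adjacent_pairs(faces: np.ndarray) -> np.ndarray:
    """Index pairs (f, g), f != g, of faces sharing at least one vertex."""
    n_f = len(faces)
    vert_faces = {}
    for fi, tri in enumerate(faces):
        for v in tri:
            vert_faces.setdefault(int(v), []).append(fi)
    pairs = set()
    for fl in vert_faces.values():
        for a in fl:
            for b in fl:
                if a != b:
                    pairs.add((a, b))
    out = np.array(sorted(pairs), dtype=np.int64)
    return out.reshape(-1, 2)


@dataclass
class BemGeometry:
    """Conductivity-independent discretization of a set of boundary meshes.

    ``blocks[l]`` maps hat coefficients on surface l to the (negated-jump
    pending) double-layer terms of every residual row; rows are pointwise at
    vertices (LC) or Galerkin-weighted (LG).  For LC the own-surface diagonal
    already carries the 2*pi closure correction.
    """

    meshes: tuple
    method: str
    offsets: np.ndarray
    blocks: list
    mass: list | None  # LG: per-surface mass matrices
    quad: list | None  # LG: per-surface (points_m, hat csr, weight*area)

    @property
    def n(self) -> int:
        return int(self.offsets[-1])

    def cols(self, l: int) -> slice:
        return slice(int(self.offsets[l]), int(self.offsets[l + 1]))


def assemble_geometry(model_or_meshes, method: str = "LC",
                      galerkin_order: int = 7, galerkin_refine_depth: int = 1) -> BemGeometry:
    """Assemble the double-layer weight blocks for a set of closed meshes."""
    if isinstance(model_or_meshes, HeadModel):
        meshes = tuple(s.mesh for s in model_or_meshes.surfaces)
    else:
        meshes = tuple(model_or_meshes)
    if method not in ("LC", "LG"):
        raise ValueError(f"method must be 'LC' or 'LG', got {method!r}")
    nps = [m.n_vertices for m in meshes]
    offsets = np.concatenate([[0], np.cumsum(nps)])
    n_tot = int(offsets[-1])
    tris_m = [m.vertices_m[m.faces] for m in meshes]

    if method == "LC":
        all_verts = np.vstack([m.vertices_m for m in meshes])
        blocks = []
        for l, mesh in enumerate(meshes):
            block = _weight_rows(all_verts, tris_m[l], mesh.faces, mesh.n_vertices)
            # closure: own-surface diagonal so each own row sums to exactly
            # 2*pi (flat-point principal value), keeping constants in the
            # null space for any consistent conductivity assignment
            rows = slice(int(offsets[l]), int(offsets[l + 1]))
            sub = block[rows]
            idx = np.arange(mesh.n_vertices)
            sub[idx, idx] = 0.0
            sub[idx, idx] = 2.0 * np.pi - sub.sum(axis=1)
            blocks.append(block)
        return BemGeometry(meshes, "LC", offsets, blocks, None, None)

    # --- Galerkin ---
    bary, wts = _kernels.triangle_rule(galerkin_order)
    quad = []
    for k, mesh in enumerate(meshes):
        t = tris_m[k]
        _, areas = _kernels.triangle_frames(t)
        pts = np.einsum("qb,fbx->fqx", bary, t).reshape(-1, 3)
        w_a = (areas[:, None] * wts[None, :]).reshape(-1)
        f_rep = np.repeat(np.arange(mesh.n_faces), len(wts))
        qbary = np.tile(bary, (mesh.n_faces, 1))
        rows = np.arange(len(pts))
        cols = mesh.faces[f_rep]
        hat = sp.csr_matrix(
            (qbary.reshape(-1), (np.repeat(rows, 3), cols.reshape(-1))),
            shape=(len(pts), mesh.n_vertices))
        quad.append((pts, hat, w_a, f_rep, qbary))

    blocks = [np.zeros((n_tot, m.n_vertices)) for m in meshes]
    for k, mesh_k in enumerate(meshes):
        pts_k, _, wa_k, f_rep_k, qbary_k = quad[k]
        rows = slice(int(offsets[k]), int(offsets[k + 1]))
        for l, mesh_l in enumerate(meshes):
            sub = np.zeros((mesh_k.n_vertices, mesh_l.n_vertices))
            _fastkernels.galerkin_block_accumulate(
                np.ascontiguousarray(pts_k), np.ascontiguousarray(f_rep_k),
                np.ascontiguousarray(qbary_k), np.ascontiguousarray(wa_k),
                np.ascontiguousarray(mesh_k.faces), np.ascontiguousarray(tris_m[l]),
                np.ascontiguousarray(mesh_l.faces), sub)
            blocks[l][rows] += sub
        # refinement of near-singular outer integrals: same-surface
        # vertex/edge-adjacent face pairs
        _refine_adjacent(blocks[k], mesh_k, tris_m[k], offsets[k],
                         galerkin_order, galerkin_refine_depth)
    mass = [_mass_matrix(tris_m[k], meshes[k].faces, meshes[k].n_vertices)
            for k in range(len(meshes))]
    return BemGeometry(meshes, "LG", offsets, blocks, mass, quad)


def _refine_adjacent(block: np.ndarray, mesh: TriMesh, tri_m: np.ndarray,
                     row_offset: int, order: int, depth: int):
    """Replace the plain-rule contribution of adjacent (outer, source) face
    pairs on the same surface by a subdivided-rule evaluation."""
    if depth <= 0:
        return
    pairs = _adjacent_pairs(mesh.faces)
    if not len(pairs):
        return
    _, areas = _kernels.triangle_frames(tri_m)
    base = _kernels.triangle_rule(order)
    fine = _kernels.refined_rule(order, depth)
    for (bary, wts), sign in ((base, -1.0), (fine, +1.0)):
        n_q = len(wts)
        batch = max(1, 200_000 // n_q)
        for lo in range(0, len(pairs), batch):
            pp = pairs[lo:lo + batch]
            f_out, f_src = pp[:, 0], pp[:, 1]
            pts = np.einsum("qb,pbx->pqx", bary, tri_m[f_out])  # (p, q, 3)
            tri_rep = np.repeat(tri_m[f_src], n_q, axis=0)
            w_src = _kernels.linear_basis_solid_angles_pairs(
                pts.reshape(-1, 3), tri_rep).reshape(len(pp), n_q, 3)
            # outer hat values = barycentric coords; integrate
            contrib = np.einsum("q,qa,pqb->pab", wts, bary, w_src)  # (p, 3, 3)
            contrib *= sign * areas[f_out][:, None, None]
            rows = (row_offset + mesh.faces[f_out])[:, :, None]
            cols = mesh.faces[f_src][:, None, :]
            np.add.at(block, (rows, cols), contrib)


# ---------------------------------------------------------------------------
# conductivity application, deflation, ISA
# ---------------------------------------------------------------------------

def _containment_matrix(meshes) -> np.ndarray:
    """inside[i, j] == True if mesh i lies inside closed mesh j (winding
    number of one vertex; surfaces are assumed disjoint)."""
    n = len(meshes)
    inside = np.zeros((n, n), bool)
    for i, mi in enumerate(meshes):
        p = mi.vertices[:1]
        for j, mj in enumerate(meshes):
            if i == j:
                continue
            w = _kernels.solid_angles(p, mj.triangles).sum() / _kernels.FOUR_PI
            inside[i, j] = w > 0.5
    return inside


@dataclass
class BemSystem:
    """A conductivity-applied, deflated (and optionally ISA-split) BEM
    operator, ready to map per-source boundary source terms to nodal
    potentials."""

    geometry: BemGeometry
    model: HeadModel
    method: str
    deflated: bool
    use_isa: bool
    isolation_surface: str | None
    _lu: tuple
    _A_shape: tuple
    _iso: dict | None

    @property
    def n(self) -> int:
        return self.geometry.n

    @property
    def vertex_surface(self) -> np.ndarray:
        """Surface index of each global vertex row."""
        out = np.empty(self.n, int)
        for l in range(len(self.geometry.meshes)):
            out[self.geometry.cols(l)] = l
        return out

    def condition_estimate(self) -> float:
        """Cheap condition proxy: ratio of extreme |U| pivots of the LU."""
        lu, _ = self._lu
        d = np.abs(np.diag(lu))
        return float(d.max() / max(d.min(), 1e-300))


def _build_operator(geo: BemGeometry, model: HeadModel) -> np.ndarray:
    jumps = np.array([s.jump for s in model.surfaces])
    sums = np.array([s.sigma_in + s.sigma_out for s in model.surfaces])
    n = geo.n
    A = np.zeros((n, n))
    for l in range(len(model.surfaces)):
        A[:, geo.cols(l)] = -jumps[l] * geo.blocks[l]
    if geo.method == "LC":
        d = np.empty(n)
        for l in range(len(model.surfaces)):
            d[geo.cols(l)] = 2.0 * np.pi * sums[l]
        A[np.arange(n), np.arange(n)] += d
    else:
        for l in range(len(model.surfaces)):
            sl = geo.cols(l)
            A[sl, sl] += (2.0 * np.pi * sums[l]) * geo.mass[l].toarray()
        # the mixed base/refined outer quadrature leaves a tiny (~1e-5
        # relative) constant-vector defect; close it on the diagonal so the
        # null space is exact and deflation is consistent
        idx = np.arange(n)
        A[idx, idx] -= A @ np.ones(n)
    return A


def _outermost_index(model: HeadModel) -> int:
    return int(np.argmax([abs(s.mesh.signed_volume()) for s in model.surfaces]))


def assemble_system(model: HeadModel, method: str = "LC", use_isa: bool = True,
                    isolation_surface: str | None = "inner_skull",
                    geometry: BemGeometry | None = None,
                    deflate: bool = True, **geo_kwargs) -> BemSystem:
    """Discretize, deflate and (optionally) ISA-split a head model.

    ``geometry`` may pass a precomputed :func:`assemble_geometry` result so
    that conductivity sweeps reuse the expensive mesh integrals.  The
    isolation surface defaults to the inner skull; if the model has no
    surface of that name (e.g. a single-shell model) ISA is disabled.
    """
    geo = geometry if geometry is not None else assemble_geometry(model, method, **geo_kwargs)
    if geo.method != method:
        raise ValueError(f"geometry was assembled for {geo.method}, not {method}")
    names = [s.name for s in model.surfaces]
    if use_isa and (isolation_surface not in names):
        if isolation_surface == "inner_skull":
            use_isa = False  # model without a skull: nothing to isolate
        else:
            raise ValueError(f"isolation surface {isolation_surface!r} not in model {names}")

    A = _build_operator(geo, model)
    n = geo.n
    outer = _outermost_index(model)
    if deflate:
        m_vec = np.zeros(n)
        sl = geo.cols(outer)
        m_vec[sl] = 1.0 / (sl.stop - sl.start)
        scale = np.abs(np.diag(A)).mean()
        A += scale * np.outer(np.ones(n), m_vec)
    lu = sla.lu_factor(A, overwrite_a=True, check_finite=False)

    iso = None
    if use_isa:
        iso = _build_isa(geo, model, isolation_surface)
    return BemSystem(geometry=geo, model=model, method=method, deflated=deflate,
                     use_isa=use_isa, isolation_surface=isolation_surface if use_isa else None,
                     _lu=lu, _A_shape=(n, n), _iso=iso)


def _build_isa(geo: BemGeometry, model: HeadModel, isolation_surface: str) -> dict:
    names = [s.name for s in model.surfaces]
    m_idx = names.index(isolation_surface)
    inside = _containment_matrix(geo.meshes)
    iso_set = [i for i in range(len(names)) if i == m_idx or inside[i, m_idx]]
    # modified conductivities: zero outside the isolation surface
    sig_in = np.array([model.surfaces[i].sigma_in for i in iso_set])
    sig_out = np.array([0.0 if i == m_idx else model.surfaces[i].sigma_out for i in iso_set])
    jumps_p = sig_in - sig_out
    sums_p = sig_in + sig_out

    n = geo.n
    iso_rows = np.concatenate([np.arange(geo.cols(i).start, geo.cols(i).stop) for i in iso_set])
    n_iso = len(iso_rows)
    loc_off = np.concatenate([[0], np.cumsum([geo.meshes[i].n_vertices for i in iso_set])])

    a_iso = np.zeros((n_iso, n_iso))
    t_full = np.zeros((n, n_iso))
    for a, i in enumerate(iso_set):
        cols_g = geo.cols(i)
        cols_l = slice(int(loc_off[a]), int(loc_off[a + 1]))
        t_full[:, cols_l] = -jumps_p[a] * geo.blocks[i]
        a_iso[:, cols_l] = -jumps_p[a] * geo.blocks[i][iso_rows]
    if geo.method == "LC":
        for a in range(len(iso_set)):
            cols_l = slice(int(loc_off[a]), int(loc_off[a + 1]))
            idx = np.arange(cols_l.start, cols_l.stop)
            a_iso[idx, idx] += 2.0 * np.pi * sums_p[a]
            t_full[iso_rows[cols_l], idx] += 2.0 * np.pi * sums_p[a]
    else:
        for a, i in enumerate(iso_set):
            cols_l = slice(int(loc_off[a]), int(loc_off[a + 1]))
            mblock = (2.0 * np.pi * sums_p[a]) * geo.mass[i].toarray()
            a_iso[cols_l, cols_l] += mblock
            t_full[iso_rows[cols_l][:, None], np.arange(cols_l.start, cols_l.stop)[None, :]] += mblock
    if geo.method == "LG":
        idx = np.arange(n_iso)
        a_iso[idx, idx] -= a_iso @ np.ones(n_iso)

    # deflate the isolated operator on its own outermost surface
    m_loc = iso_set.index(m_idx)
    m_vec = np.zeros(n_iso)
    sl = slice(int(loc_off[m_loc]), int(loc_off[m_loc + 1]))
    m_vec[sl] = 1.0 / (sl.stop - sl.start)
    a_iso += np.abs(np.diag(a_iso)).mean() * np.outer(np.ones(n_iso), m_vec)
    lu_iso = sla.lu_factor(a_iso, overwrite_a=True, check_finite=False)
    return {"rows": iso_rows, "lu": lu_iso, "transform": t_full}


# ---------------------------------------------------------------------------
# source terms and solves
# ---------------------------------------------------------------------------

def _infinite_medium_terms(points_m: np.ndarray, positions_m: np.ndarray,
                           moments: np.ndarray) -> np.ndarray:
    """4*pi*sigma_0*phi_inf(points) = p . (r - r0) / |r - r0|^3, (P x S)."""
    y = points_m[:, None, :] - positions_m[None, :, :]
    r3 = np.linalg.norm(y, axis=-1) ** 3
    return np.einsum("psx,sx->ps", y / r3[..., None], moments)


def source_terms(system: BemSystem, positions_m, moments) -> np.ndarray:
    """Boundary source-term matrix (n_vertices x n_sources) for dipoles.

    LC evaluates the infinite-medium term at the vertices; LG integrates it
    against the hat functions (with subdivision refinement of faces close to
    a dipole).  With ISA enabled the raw terms are replaced by the
    back-substituted isolated-problem representation.
    """
    positions_m = np.atleast_2d(np.asarray(positions_m, float))
    moments = np.atleast_2d(np.asarray(moments, float))
    geo = system.geometry
    if geo.method == "LC":
        all_verts = np.vstack([m.vertices_m for m in geo.meshes])
        s = _infinite_medium_terms(all_verts, positions_m, moments)
    else:
        s = np.zeros((geo.n, len(positions_m)))
        for k, mesh in enumerate(geo.meshes):
            pts, hat, w_a, _, _ = geo.quad[k]
            vals = _infinite_medium_terms(pts, positions_m, moments)
            s[geo.cols(k)] = hat.T @ (w_a[:, None] * vals)
            _refine_source_terms(s, geo, k, positions_m, moments)
    if system.use_isa:
        iso = system._iso
        phi0 = sla.lu_solve(iso["lu"], s[iso["rows"]], check_finite=False)
        s = iso["transform"] @ phi0
    return s


def _refine_source_terms(s, geo: BemGeometry, k: int, positions_m, moments):
    """Subdivide the outer quadrature of faces that are close to a dipole."""
    mesh = geo.meshes[k]
    tri_m = mesh.vertices_m[mesh.faces]
    _, areas = _kernels.triangle_frames(tri_m)
    tsl = float(np.sqrt(areas.mean() * 4 / np.sqrt(3)))
    cent = tri_m.mean(axis=1)
    d = np.linalg.norm(cent[:, None, :] - positions_m[None, :, :], axis=-1)
    base_bary, base_wts = _kernels.triangle_rule(7)
    for depth, lo_f, hi_f in ((4, 0.0, 1.0), (3, 1.0, 2.0), (2, 2.0, 4.0)):
        fine_bary, fine_wts = _kernels.refined_rule(7, depth)
        fsel, ssel = np.nonzero((d >= lo_f * tsl) & (d < hi_f * tsl))
        if not len(fsel):
            continue
        for (bary, wts), sign in (((base_bary, base_wts), -1.0),
                                  ((fine_bary, fine_wts), +1.0)):
            pts = np.einsum("qb,pbx->pqx", bary, tri_m[fsel])
            y = pts - positions_m[ssel][:, None, :]
            r3 = np.linalg.norm(y, axis=-1) ** 3
            vals = np.einsum("pqx,px->pq", y / r3[..., None], moments[ssel])
            contrib = sign * areas[fsel][:, None] * np.einsum("q,qa,pq->pa", wts, bary, vals)
            np.add.at(s, ((geo.cols(k).start + mesh.faces[fsel])[:, :], ssel[:, None]), contrib)


def solve_potentials(system: BemSystem, terms: np.ndarray) -> np.ndarray:
    """Nodal boundary potentials (n_vertices x n_sources) for source terms."""
    terms = np.asarray(terms, float)
    if terms.shape[0] != system.n:
        raise ValueError(f"expected {system.n} vertex rows, got {terms.shape[0]}")
    if not system.deflated:
        raise RuntimeError("the undeflated operator is singular (constant null "
                           "space); assemble with deflate=True")
    return sla.lu_solve(system._lu, terms, check_finite=False)


def transfer_matrix(system: BemSystem, sensor_weights: np.ndarray) -> np.ndarray:
    """Channel-side transfer matrix T with T @ terms == sensors @ potentials.

    Solves the adjoint system once per channel so that leadfields for any
    number of sources cost one matrix product.
    """
    sensor_weights = np.atleast_2d(np.asarray(sensor_weights, float))
    if sensor_weights.size and sensor_weights.shape[1] != system.n:
        raise ValueError(f"sensor weights must have {system.n} columns")
    if sensor_weights.shape[0] == 0:
        return np.zeros((0, system.n))
    if not system.deflated:
        raise RuntimeError("the undeflated operator is singular (constant null "
                           "space); assemble with deflate=True")
    return sla.lu_solve(system._lu, sensor_weights.T, trans=1, check_finite=False).T
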