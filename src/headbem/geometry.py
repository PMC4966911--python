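"""Triangle surface meshes: data structure, synthetic generators, statistics, I/O.

All meshes in this module carry vertex coordinates in **millimetres**; field
computations convert to SI metres in one place (``TriMesh.vertices_m``).
Closed, consistently outward-oriented 2-manifolds are assumed by the solver;
:func:`mesh_statistics` reports the corresponding flags instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.special import sph_harm_y

__all__ = [
    "TriMesh",
    "MeshStats",
    "build_icosphere",
    "perturb_sphere",
    "mesh_statistics",
    "read_mesh",
    "write_mesh",
]

#: millimetres per metre — the single unit-conversion constant
MM_PER_M = 1000.0


@dataclass(frozen=True)
class TriMesh:
    """A closed, oriented triangle surface.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in millimetres.
    faces : (F, 3) int array
        Vertex index triples, counter-clockwise seen from outside
        (outward orientation).
    name : str
        Label, e.g. ``"pial"`` or ``"scalp"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "surface"

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    # -- derived geometry ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def vertices_m(self) -> np.ndarray:
        """Vertex positions in metres (SI), for field computations."""
        return self.vertices / MM_PER_M

    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates in mm."""
        return self.vertices[self.faces]

    def face_normals_areas(self):
        """Unit outward face normals and face areas (mm^2)."""
        t = self.triangles
        cr = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        a2 = np.linalg.norm(cr, axis=1)
        areas = 0.5 * a2
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = cr / a2[:, None]
        return normals, areas

    def edges_unique(self) -> np.ndarray:
        """(E, 2) sorted unique undirected edges."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3); positive for outward orientation."""
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def translated(self, offset) -> "TriMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, float))

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass(frozen=True)
class MeshStats:
    """Summary statistics of a surface mesh (``mean_tsl`` is the mean
    triangle-side length over unique edges, the usual mesh-density measure)."""

    vertex_count: int
    face_count: int
    mean_tsl: float  # mm
    total_area: float  # mm^2
    signed_volume: float  # mm^3
    is_closed: bool
    is_outward: bool


def build_icosphere(subdivision_level: int, radius: float, center=(0.0, 0.0, 0.0),
                    name: str = "icosphere") -> TriMesh:
    """Subdivided icosahedron projected to a sphere.

    ``subdivision_level`` 0 gives the icosahedron (12 vertices); each level
    quadruples the face count, so the vertex count is ``10 * 4**level + 2``
    and the mean triangle-side length roughly halves per level.

    Parameters are in millimetres.
    """
    if subdivision_level < 0 or int(subdivision_level) != subdivision_level:
        raise ValueError(f"subdivision_level must be a non-negative integer, got {subdivision_level}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    m = _trimesh.creation.icosphere(subdivisions=int(subdivision_level), radius=float(radius))
    verts = np.asarray(m.vertices, float) + np.asarray(center, float)
    return TriMesh(verts, np.asarray(m.faces, np.int64), name=name)


def _random_band_limited(directions: np.ndarray, max_degree: int, rng: np.random.Generator) -> np.ndarray:
    """Random smooth function on the unit sphere with spherical-harmonic content
    up to ``max_degree``, evaluated at unit ``directions``; zero-degree term is
    excluded so the perturbation has no net inflation."""
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    f = np.zeros(len(directions))
    for ell in range(1, max_degree + 1):
        for m in range(0, ell + 1):
            y_lm = sph_harm_y(ell, m, theta, phi)
            a, b = rng.standard_normal(2)
            if m == 0:
                f += a * y_lm.real
            else:
                f += a * np.sqrt(2.0) * y_lm.real + b * np.sqrt(2.0) * y_lm.imag
    return f


def perturb_sphere(mesh: TriMesh, amplitude: float, max_degree: int = 4,
                   seed: int = 0, center=(0.0, 0.0, 0.0)) -> TriMesh:
    """Radially displace a sphere-topology mesh by a random band-limited field.

    Each vertex at radius r moves to ``r * (1 + f(theta, phi))`` where ``f`` is a
    random smooth function with ``|f| <= amplitude``, deterministic given
    ``seed``.  Amplitudes of 0.3 or more are refused (self-intersection risk).
    """
    if not 0.0 <= amplitude < 0.3:
        raise ValueError(f"amplitude must be in [0, 0.3), got {amplitude}")
    if amplitude == 0.0:
        return mesh
    c = np.asarray(center, float)
    rel = mesh.vertices - c
    r = np.linalg.norm(rel, axis=1)
    if np.any(r <= 0):
        raise ValueError("a vertex coincides with the perturbation center")
    dirs = rel / r[:, None]
    rng = np.random.default_rng(seed)
    f = _random_band_limited(dirs, max_degree, rng)
    peak = np.abs(f).max()
    if peak > 0:
        f *= amplitude / peak
    verts = c + rel * (1.0 + f)[:, None]
    return replace(mesh, vertices=verts, name=mesh.name + "_perturbed")


def _closed_and_outward(mesh: TriMesh):
    """Edge-incidence closedness test and signed-volume orientation test."""
    e_dir = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    order = np.lexsort((np.maximum(e_dir[:, 0], e_dir[:, 1]), np.minimum(e_dir[:, 0], e_dir[:, 1])))
    e_sorted = e_dir[order]
    und = np.sort(e_sorted, axis=1)
    # closed 2-manifold: every undirected edge appears exactly twice, and with
    # opposite directions (consistent orientation)
    if len(und) % 2:
        return False, False
    pairs_match = np.all(und[0::2] == und[1::2])
    opposite = np.all(e_sorted[0::2] == e_sorted[1::2, ::-1])
    closed = bool(pairs_match)
    consistent = bool(pairs_match and opposite)
    outward = consistent and mesh.signed_volume() > 0
    return closed, outward


def mesh_statistics(mesh: TriMesh) -> MeshStats:
    """Vertex/face counts, mean triangle-side length, area, volume, and
    closedness/orientation flags."""
    edges = mesh.edges_unique()
    lengths = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    _, areas = mesh.face_normals_areas()
    closed, outward = _closed_and_outward(mesh)
    return MeshStats(
        vertex_count=mesh.n_vertices,
        face_count=mesh.n_faces,
        mean_tsl=float(lengths.mean()) if len(lengths) else 0.0,
        total_area=float(areas.sum()),
        signed_volume=mesh.signed_volume(),
        is_closed=closed,
        is_outward=outward,
    )


_KNOWN_FORMATS = {"off", "stl", "ply"}


def read_mesh(path, file_format: str | None = None, name: str | None = None,
              fix_orientation: bool = True) -> TriMesh:
    """Read a triangle mesh (OFF, STL or PLY; coordinates in mm).

    STL stores triangle soups, so vertices are merged at 1e-6 mm.  If the file
    is closed but inward-oriented, faces are flipped to the outward convention
    (with a warning) unless ``fix_orientation`` is false.
    """
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {sorted(_KNOWN_FORMATS)}")
    try:
        m = _trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ValueError(f"cannot parse {path} as {fmt.upper()}: {exc}") from exc
    if isinstance(m, _trimesh.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise ValueError(f"cannot parse {path}: no geometry found")
        m = geoms[0]
    if m.vertices.size == 0 or m.faces.size == 0:
        raise ValueError(f"cannot parse {path}: empty mesh")
    if fmt == "stl":
        m.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh = TriMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64),
                   name=name or path.stem)
    closed, outward = _closed_and_outward(mesh)
    if fix_orientation and closed and not outward and mesh.signed_volume() < 0:
        import warnings

        warnings.warn(f"{path.name}: inward-oriented surface; flipping faces to outward",
                      stacklevel=2)
        mesh = replace(mesh, faces=mesh.faces[:, ::-1])
    return mesh


def write_mesh(mesh: TriMesh, path, file_format: str | None = None) -> None:
    """Write a mesh as OFF, STL (ASCII) or PLY (ASCII), coordinates in mm.

    All three writers emit full-precision (%.17g) coordinates so that a
    write-then-read roundtrip preserves vertices far below the 1e-6 mm
    contract (STL roundtrips reconstruct shared vertices by merging the
    per-facet corners, an inherent property of that format).
    """
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _KNOWN_FORMATS:
        raise ValueError(f"unknown mesh format {fmt!r}; expected one of {sorted(_KNOWN_FORMATS)}")
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        if fmt == "off":
            fh.write("OFF\n")
            fh.write(f"{len(v)} {len(f)} 0\n")
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        elif fmt == "ply":
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(v)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(f)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        else:  # ascii STL: per-facet corner soup with normals
            normals, _ = mesh.face_normals_areas()
            fh.write(f"solid {mesh.name}\n")
            for tri, nrm in zip(f, normals):
                fh.write(f"  facet normal {nrm[0]:.17g} {nrm[1]:.17g} {nrm[2]:.17g}\n")
                fh.write("    outer loop\n")
                for idx in tri:
                    p = v[idx]
                    fh.write(f"      vertex {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {mesh.name}\n")
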