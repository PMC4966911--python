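"""Dipole sources, source spaces, and EEG/MEG sensor arrays.

The primary current is discretized into point current dipoles; sensor models
follow common MEG/EEG practice: EEG electrodes are points snapped onto the
scalp mesh (potentials interpolated with the BEM linear basis, i.e.
barycentrically within the containing triangle), and MEG magnetometers are
square pickup coils whose flux is approximated by the average normal field
over a 2x2 Gauss grid on the coil (four integration points, weights 1/4).

Surrogate array layouts use deterministic Fibonacci-lattice caps with the
channel counts of common whole-head systems (256 electrodes, 102
magnetometers), so topography dimensionalities match experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import MM_PER_M, TriMesh
from .headmodel import HeadModel

__all__ = [
    "Dipole",
    "SourceSpace",
    "ElectrodeArray",
    "MagnetometerArray",
    "MU0",
    "dipole_potential_infinite",
    "dipole_primary_field",
    "build_source_space",
    "build_sensor_arrays",
    "electrode_potentials",
    "magnetometer_readings",
]

#: vacuum permeability, T*m/A
MU0 = 4e-7 * np.pi

#: default dipole magnitude, A*m (10 nA*m; topography metrics are
#: scale-invariant, so this is cosmetic)
DEFAULT_DIPOLE_MOMENT = 1e-8


@dataclass(frozen=True)
class Dipole:
    """Current dipole: position (m) and moment (A*m)."""

    position_m: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position_m", np.asarray(self.position_m, float).reshape(3))
        object.__setattr__(self, "moment", np.asarray(self.moment, float).reshape(3))


@dataclass(frozen=True)
class SourceSpace:
    """A set of dipoles with a reproducible construction recipe."""

    positions_m: np.ndarray  # (n, 3)
    moments: np.ndarray      # (n, 3), A*m
    orientation_mode: str = "random"
    seed: int = 0

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.positions_m, float))
        m = np.atleast_2d(np.asarray(self.moments, float))
        if p.shape != m.shape or p.shape[1] != 3:
            raise ValueError("positions and moments must both be (n, 3)")
        object.__setattr__(self, "positions_m", p)
        object.__setattr__(self, "moments", m)

    def __len__(self) -> int:
        return len(self.positions_m)

    @property
    def dipoles(self):
        return [Dipole(p, m) for p, m in zip(self.positions_m, self.moments)]


@dataclass(frozen=True)
class ElectrodeArray:
    """EEG electrodes snapped onto a scalp mesh.

    ``faces``/``bary`` record the containing triangle and barycentric
    coordinates of each electrode, which define the linear-basis
    interpolation of the nodal potentials.
    """

    positions_m: np.ndarray   # (C, 3), on the scalp mesh
    faces: np.ndarray         # (C,) face index on the scalp mesh
    bary: np.ndarray          # (C, 3)
    mesh: TriMesh
    names: tuple = ()

    def __len__(self) -> int:
        return len(self.positions_m)

    def interpolation_matrix(self) -> np.ndarray:
        """(C x V_scalp) barycentric interpolation weights (rows sum to 1)."""
        w = np.zeros((len(self), self.mesh.n_vertices))
        tri = self.mesh.faces[self.faces]
        rows = np.arange(len(self))[:, None]
        np.add.at(w, (rows, tri), self.bary)
        return w


@dataclass(frozen=True)
class MagnetometerArray:
    """Square-coil magnetometers: center, unit normal, and the 2x2 Gauss
    integration points in the coil plane (weights sum to 1)."""

    centers_m: np.ndarray      # (C, 3)
    normals: np.ndarray        # (C, 3) unit
    coil_side_m: float
    integration_points_m: np.ndarray  # (C, 4, 3)
    weights: np.ndarray        # (4,)
    names: tuple = ()

    def __len__(self) -> int:
        return len(self.centers_m)


# ---------------------------------------------------------------------------
# elementary fields
# ---------------------------------------------------------------------------

def _as_dipole(dipole) -> Dipole:
    if isinstance(dipole, Dipole):
        return dipole
    pos, mom = dipole
    return Dipole(pos, mom)


def dipole_potential_infinite(dipole, points_m, sigma: float) -> np.ndarray:
    """Infinite-medium potential phi_inf(r) = p.(r-r0) / (4 pi sigma |r-r0|^3)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = _as_dipole(dipole)
    pts = np.atleast_2d(np.asarray(points_m, float))
    y = pts - d.position_m
    r = np.linalg.norm(y, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("evaluation point coincides with the dipole")
    return (y @ d.moment) / (4.0 * np.pi * sigma * r ** 3)


def dipole_primary_field(dipole, points_m) -> np.ndarray:
    """Primary (infinite-medium) magnetic field of a current dipole,
    B_inf(r) = (mu0 / 4 pi) p x (r - r0) / |r - r0|^3, in tesla."""
    d = _as_dipole(dipole)
    pts = np.atleast_2d(np.asarray(points_m, float))
    y = pts - d.position_m
    r = np.linalg.norm(y, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("evaluation point coincides with the dipole")
    return MU0 / (4.0 * np.pi) * np.cross(d.moment[None, :], y) / (r ** 3)[:, None]


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int, z_range=(-1.0, 1.0)) -> np.ndarray:
    """Deterministic quasi-uniform directions on a spherical cap/band."""
    i = np.arange(n) + 0.5
    z = z_range[1] + (z_range[0] - z_range[1]) * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def build_source_space(n: int, radius_range_mm=(58.0, 76.5),
                       orientation_mode: str = "random", seed: int = 0,
                       center_mm=(0.0, 0.0, 0.0), brain_radius_mm: float = 78.0,
                       min_depth_mm: float = 1.5,
                       moment_magnitude: float = DEFAULT_DIPOLE_MOMENT) -> SourceSpace:
    """Quasi-uniform dipoles in a spherical shell of the brain compartment.

    Directions follow a Fibonacci lattice, radii are drawn uniformly over
    ``radius_range_mm`` (seeded), and every dipole keeps at least
    ``min_depth_mm`` of tissue to the brain boundary.  ``orientation_mode``
    is ``radial`` (surrogate for cortical-normal sources in a sphere),
    ``tangential``, or ``random``.
    """
    if n <= 0:
        raise ValueError("need at least one dipole")
    lo, hi = float(radius_range_mm[0]), float(radius_range_mm[1])
    if not 0.0 <= lo <= hi:
        raise ValueError(f"bad radius range {radius_range_mm}")
    if hi > brain_radius_mm - min_depth_mm + 1e-9:
        raise ValueError(f"radius range up to {hi} mm violates the minimum depth "
                         f"{min_depth_mm} mm below the brain boundary at {brain_radius_mm} mm")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(n)
    radii = rng.uniform(lo, hi, n)
    pos_mm = np.asarray(center_mm, float) + dirs * radii[:, None]

    if orientation_mode == "radial":
        mom = dirs.copy()
    elif orientation_mode == "tangential":
        ref = rng.standard_normal((n, 3))
        mom = np.cross(dirs, ref)
        bad = np.linalg.norm(mom, axis=1) < 1e-12
        if np.any(bad):
            mom[bad] = np.cross(dirs[bad], [1.0, 0.0, 0.0])
        mom /= np.linalg.norm(mom, axis=1)[:, None]
    elif orientation_mode == "random":
        mom = rng.standard_normal((n, 3))
        mom /= np.linalg.norm(mom, axis=1)[:, None]
    else:
        raise ValueError(f"orientation_mode must be radial|tangential|random, "
                         f"got {orientation_mode!r}")
    return SourceSpace(pos_mm / MM_PER_M, mom * moment_magnitude,
                       orientation_mode=orientation_mode, seed=seed)


def build_sensor_arrays(model: HeadModel, n_electrodes: int = 256,
                        n_magnetometers: int = 102,
                        helmet_radius_mm: float | None = None,
                        coil_side_mm: float = 21.0, seed: int = 0):
    """Surrogate EEG + MEG arrays for a head model.

    Electrodes: Fibonacci lattice over the upper scalp (directions with
    z > -0.25 * scalp radius), snapped to the scalp mesh.  Magnetometers:
    Fibonacci lattice on an upper helmet cap of radius ``helmet_radius_mm``
    (default scalp radius + 25 mm), coil normals radial, 2x2 Gauss
    integration points.  Deterministic; ``seed`` reserved for randomized
    layouts.
    """
    scalp = model.surfaces[_outermost(model)].mesh
    center = scalp.vertices.mean(axis=0)
    scalp_r = float(np.linalg.norm(scalp.vertices - center, axis=1).mean())
    if helmet_radius_mm is None:
        helmet_radius_mm = scalp_r + 25.0
    if helmet_radius_mm <= scalp_r:
        raise ValueError(f"helmet radius {helmet_radius_mm} mm must exceed the "
                         f"scalp radius {scalp_r:.1f} mm")

    # electrodes: directions on the upper cap, snapped to the mesh
    dirs = _fibonacci_directions(n_electrodes, z_range=(-0.25, 1.0))
    raw_mm = center + dirs * (1.05 * scalp_r)
    closest, _, fidx, bary = _kernels.closest_point_on_triangles(raw_mm, scalp.triangles)
    electrodes = ElectrodeArray(
        positions_m=closest / MM_PER_M, faces=fidx, bary=bary, mesh=scalp,
        names=tuple(f"EEG{i + 1:03d}" for i in range(n_electrodes)))

    # magnetometers: upper helmet cap, radial normals
    mdirs = _fibonacci_directions(n_magnetometers, z_range=(-0.15, 1.0))
    centers_mm = center + mdirs * helmet_radius_mm
    normals = mdirs
    side_m = coil_side_mm / MM_PER_M
    g = side_m / (2.0 * np.sqrt(3.0))  # 2-point Gauss offset on [-side/2, side/2]
    u = np.cross(normals, np.where(np.abs(normals[:, 2:3]) < 0.9,
                                   [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]))
    u /= np.linalg.norm(u, axis=1)[:, None]
    v = np.cross(normals, u)
    offs = np.array([[+1, +1], [+1, -1], [-1, +1], [-1, -1]], float) * g
    ipts = (centers_mm[:, None, :] / MM_PER_M
            + offs[None, :, 0:1] * u[:, None, :] + offs[None, :, 1:2] * v[:, None, :])
    magnetometers = MagnetometerArray(
        centers_m=centers_mm / MM_PER_M, normals=normals, coil_side_m=side_m,
        integration_points_m=ipts, weights=np.full(4, 0.25),
        names=tuple(f"MEG{i + 1:03d}" for i in range(n_magnetometers)))
    return electrodes, magnetometers


def _outermost(model: HeadModel) -> int:
    return int(np.argmax([abs(s.mesh.signed_volume()) for s in model.surfaces]))


# ---------------------------------------------------------------------------
# sensor evaluation
# ---------------------------------------------------------------------------

def electrode_potentials(surface_potentials: np.ndarray,
                         electrodes: ElectrodeArray) -> np.ndarray:
    """Interpolate nodal scalp potentials to the electrodes (channels x sources).

    Uses the linear BEM basis: barycentric weights within the containing
    triangle (exact for affine fields)."""
    vals = np.asarray(surface_potentials, float)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[0] != electrodes.mesh.n_vertices:
        raise ValueError(f"expected {electrodes.mesh.n_vertices} scalp nodal values, "
                         f"got {vals.shape[0]}")
    tri = electrodes.mesh.faces[electrodes.faces]  # (C, 3)
    return np.einsum("cv,cvs->cs", electrodes.bary, vals[tri])


def magnetometer_readings(field_at_integration_points: np.ndarray,
                          array: MagnetometerArray) -> np.ndarray:
    """Coil readings (T): weighted mean of B . normal over integration points.

    ``field_at_integration_points`` has shape (C, 4, 3) or (C, 4, 3, S).
    """
    b = np.asarray(field_at_integration_points, float)
    squeeze = b.ndim == 3
    if squeeze:
        b = b[..., None]
    if b.shape[:2] != (len(array), len(array.weights)):
        raise ValueError(f"expected field shaped ({len(array)}, {len(array.weights)}, 3[, S])")
    bn = np.einsum("cqxs,cx->cqs", b, array.normals)
    out = np.einsum("cqs,q->cs", bn, array.weights)
    return out[:, 0] if squeeze else out
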