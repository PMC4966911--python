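"""Piecewise-homogeneous, isotropic volume-conductor models.

A :class:`HeadModel` is an ordered list of closed boundary surfaces, each
carrying the conductivity just inside (``sigma_in``) and just outside
(``sigma_out``).  This per-surface representation needs no containment tree,
so nested (concentric-shell) and non-nested (extra disjoint blobs) topologies
are handled uniformly; the only quantity the solver ever uses is the
conductivity jump ``sigma_in - sigma_out`` of each surface.

The skull is parameterized by the soft-tissue-to-skull resistivity ratio K:
``sigma_skull = sigma_soft / K`` with soft tissue at 0.33 S/m.  Literature
estimates put K roughly between 20 and 80.  CSF is 1.79 S/m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .geometry import TriMesh, build_icosphere, mesh_statistics, perturb_sphere

__all__ = [
    "SIGMA_SOFT",
    "SIGMA_CSF",
    "DEFAULT_RADII_MM",
    "DEFAULT_MESH_LEVELS",
    "BoundarySurface",
    "HeadModel",
    "ValidationReport",
    "build_layered_sphere_model",
    "build_nonnested_test_model",
    "validate_model",
]

#: soft tissue (brain, scalp) conductivity, S/m
SIGMA_SOFT = 0.33
#: cerebrospinal fluid conductivity, S/m
SIGMA_CSF = 1.79

#: default surrogate radii in mm: pial / inner skull / outer skull / scalp.
#: 3 mm CSF, 6 mm skull and 5 mm scalp layers — plausible adult dimensions.
DEFAULT_RADII_MM = {"pial": 78.0, "inner_skull": 81.0, "outer_skull": 87.0, "scalp": 92.0}

#: default icosphere subdivision per surface
DEFAULT_MESH_LEVELS = {"pial": 3, "inner_skull": 3, "outer_skull": 3, "scalp": 3}


@dataclass(frozen=True)
class BoundarySurface:
    """A conductivity boundary: a closed mesh plus the conductivities of the
    compartments immediately inside and outside it."""

    mesh: TriMesh
    sigma_in: float
    sigma_out: float

    def __post_init__(self):
        if self.sigma_in < 0 or self.sigma_out < 0:
            raise ValueError("conductivities must be non-negative")

    @property
    def jump(self) -> float:
        """Conductivity jump sigma_in - sigma_out (S/m), the coupling weight
        of this surface in the potential and Geselowitz equations."""
        return self.sigma_in - self.sigma_out

    @property
    def name(self) -> str:
        return self.mesh.name


@dataclass(frozen=True)
class HeadModel:
    """Ordered boundary surfaces (innermost first by convention) with the
    skull resistivity ratio K used to build them (if applicable)."""

    surfaces: tuple
    K: float | None = None
    kind: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "surfaces", tuple(self.surfaces))
        if not self.surfaces:
            raise ValueError("a head model needs at least one surface")

    @property
    def labels(self):
        return [s.name for s in self.surfaces]

    @property
    def n_vertices(self) -> int:
        return sum(s.mesh.n_vertices for s in self.surfaces)

    def surface(self, name: str) -> BoundarySurface:
        for s in self.surfaces:
            if s.name == name:
                return s
        raise KeyError(f"no surface named {name!r}; have {self.labels}")

    def surface_index(self, name: str) -> int:
        for i, s in enumerate(self.surfaces):
            if s.name == name:
                return i
        raise KeyError(f"no surface named {name!r}; have {self.labels}")

    def with_conductivities(self, sigma_in=None, sigma_out=None) -> "HeadModel":
        """Copy with per-surface conductivities replaced (dicts name->value)."""
        sigma_in = sigma_in or {}
        sigma_out = sigma_out or {}
        new = []
        for s in self.surfaces:
            new.append(replace(s, sigma_in=sigma_in.get(s.name, s.sigma_in),
                               sigma_out=sigma_out.get(s.name, s.sigma_out)))
        return replace(self, surfaces=tuple(new))


def _sphere_conductivities(kind: str, K: float, brain_scale: float = 1.0):
    sigma_brain = SIGMA_SOFT * brain_scale
    sigma_skull = SIGMA_SOFT / K
    if kind == "4C":
        return {
            "pial": (sigma_brain, SIGMA_CSF),
            "inner_skull": (SIGMA_CSF, sigma_skull),
            "outer_skull": (sigma_skull, SIGMA_SOFT),
            "scalp": (SIGMA_SOFT, 0.0),
        }
    if kind == "3S":
        # the CSF volume is labeled as brain: the brain compartment extends
        # to the inner skull and the pial boundary disappears
        return {
            "inner_skull": (sigma_brain, sigma_skull),
            "outer_skull": (sigma_skull, SIGMA_SOFT),
            "scalp": (SIGMA_SOFT, 0.0),
        }
    raise ValueError(f"kind must be '4C' or '3S', got {kind!r}")


def build_layered_sphere_model(kind: str = "4C", K: float = 50.0,
                               radii_mm: dict | None = None,
                               center_mm=(0.0, 0.0, 0.0),
                               mesh_levels: dict | None = None,
                               perturbation_amplitude: float = 0.0,
                               perturbation_seed: int = 0,
                               perturbation_max_degree: int = 4,
                               brain_scale: float = 1.0) -> HeadModel:
    """Concentric-sphere surrogate head model.

    ``kind='4C'`` builds brain/CSF/skull/scalp with boundaries pial, inner
    skull, outer skull and scalp; ``kind='3S'`` omits the pial/CSF boundary.
    Conductivities: brain and scalp 0.33 S/m, CSF 1.79 S/m, skull ``0.33/K``.

    A nonzero ``perturbation_amplitude`` applies the same random band-limited
    relative radial displacement to every surface (seeded, deterministic),
    producing a non-spherical but still non-intersecting model — useful
    because MEG is insensitive to conductivity in exactly spherical geometry.

    ``brain_scale`` multiplies the brain conductivity (conductivity-based
    compensation variant for omitted CSF).
    """
    if K <= 0:
        raise ValueError(f"K must be positive, got {K}")
    radii = dict(DEFAULT_RADII_MM, **(radii_mm or {}))
    levels = dict(DEFAULT_MESH_LEVELS, **(mesh_levels or {}))
    order4 = ["pial", "inner_skull", "outer_skull", "scalp"]
    rr = [radii[n] for n in order4]
    if not all(a < b for a, b in zip(rr, rr[1:])):
        raise ValueError(f"radii must increase pial < inner_skull < outer_skull < scalp, got {rr}")
    sigmas = _sphere_conductivities(kind, K, brain_scale)
    names = order4 if kind == "4C" else order4[1:]
    surfs = []
    for name in names:
        mesh = build_icosphere(levels[name], radii[name], center_mm, name=name)
        if perturbation_amplitude > 0:
            mesh = replace_name(perturb_sphere(mesh, perturbation_amplitude,
                                               perturbation_max_degree,
                                               perturbation_seed, center_mm), name)
        s_in, s_out = sigmas[name]
        surfs.append(BoundarySurface(mesh, s_in, s_out))
    return HeadModel(tuple(surfs), K=K, kind=kind)


def replace_name(mesh: TriMesh, name: str) -> TriMesh:
    return replace(mesh, name=name)


def build_nonnested_test_model(K: float = 50.0, blob_radius_mm: float = 15.0,
                               blob_offset_mm: float = 60.0,
                               central_radius_mm: float = 40.0,
                               blob_level: int = 2,
                               mesh_levels: dict | None = None,
                               blob_sigma_in: float = SIGMA_SOFT) -> HeadModel:
    """Non-nested five-sub-volume surrogate: 4-C spheres plus two brain blobs.

    The central brain sphere is shrunk to ``central_radius_mm`` so that a
    roomy CSF-labelled region extends to the inner skull, and two disjoint
    brain-conductivity spheres (radius ``blob_radius_mm``, centers at
    ±``blob_offset_mm`` on the x axis) float in it — a surrogate for a
    separately meshed cerebellum.  All six surfaces are mutually disjoint; the
    blob boundaries have ``sigma_in`` brain and ``sigma_out`` CSF, so the
    model is non-nested but still fully described by per-surface conductivity
    pairs.
    """
    if blob_offset_mm - blob_radius_mm <= central_radius_mm:
        raise ValueError("blobs would touch the central brain sphere")
    if blob_offset_mm + blob_radius_mm >= DEFAULT_RADII_MM["inner_skull"]:
        raise ValueError("blobs would touch the inner skull")
    radii = dict(DEFAULT_RADII_MM, pial=central_radius_mm)
    model = build_layered_sphere_model("4C", K=K, radii_mm=radii, mesh_levels=mesh_levels)
    surfs = list(model.surfaces)
    for sign, tag in ((1.0, "blob_pos"), (-1.0, "blob_neg")):
        center = (sign * blob_offset_mm, 0.0, 0.0)
        mesh = build_icosphere(blob_level, blob_radius_mm, center, name=tag)
        surfs.append(BoundarySurface(mesh, blob_sigma_in, SIGMA_CSF))
    return HeadModel(tuple(surfs), K=K, kind="4C_nonnested")


@dataclass(frozen=True)
class ValidationReport:
    closed: dict
    outward: dict
    outermost_nonconductor: bool
    conductivity_consistent: bool
    disjoint: dict
    problems: tuple

    @property
    def ok(self) -> bool:
        return not self.problems


def _winding_fraction(points_mm: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """Winding number (solid angle / 4pi) of ``mesh`` at each point."""
    sa = _kernels.solid_angles(points_mm, mesh.triangles)
    return sa.sum(axis=1) / _kernels.FOUR_PI


def surface_contains(mesh: TriMesh, points_mm: np.ndarray) -> np.ndarray:
    """Boolean inside/outside classification by winding number."""
    return _winding_fraction(np.atleast_2d(points_mm), mesh) > 0.5


def validate_model(model: HeadModel, strict: bool = False,
                   n_spot_points: int = 64, seed: int = 0) -> ValidationReport:
    """Check closedness, orientation, mutual disjointness (winding-number spot
    check on vertex subsets) and conductivity consistency.

    With ``strict`` any failure raises; otherwise the report carries flags.
    """
    problems = []
    closed, outward = {}, {}
    for s in model.surfaces:
        st = mesh_statistics(s.mesh)
        closed[s.name] = st.is_closed
        outward[s.name] = st.is_outward
        if not st.is_closed:
            problems.append(f"surface {s.name!r} is not a closed 2-manifold")
        elif not st.is_outward:
            problems.append(f"surface {s.name!r} is not outward-oriented")

    outermost_ok = True
    # surfaces whose winding number w.r.t. every other surface is 0 everywhere
    # are outermost candidates; simpler: the surface not contained in any other
    rng = np.random.default_rng(seed)
    verts_subset = {}
    for s in model.surfaces:
        idx = rng.choice(s.mesh.n_vertices, size=min(n_spot_points, s.mesh.n_vertices),
                         replace=False)
        verts_subset[s.name] = s.mesh.vertices[idx]

    disjoint = {}
    containment = {}
    names = model.labels
    for i, si in enumerate(model.surfaces):
        for j, sj in enumerate(model.surfaces):
            if i == j:
                continue
            frac = _winding_fraction(verts_subset[si.name], sj.mesh.translated([0, 0, 0]))
            inside = frac > 0.5
            if inside.all():
                containment[(si.name, sj.name)] = True
                disjoint[(si.name, sj.name)] = True
            elif (~inside).all():
                containment[(si.name, sj.name)] = False
                disjoint[(si.name, sj.name)] = True
            else:
                disjoint[(si.name, sj.name)] = False
                problems.append(f"surfaces {si.name!r} and {sj.name!r} intersect "
                                f"(mixed winding numbers)")

    # outermost = a surface contained in no other; it must border non-conductor
    for i, s in enumerate(model.surfaces):
        contained_anywhere = any(containment.get((s.name, o), False)
                                 for o in names if o != s.name)
        if not contained_anywhere:
            if s.sigma_out != 0.0:
                outermost_ok = False
                problems.append(f"outermost surface {s.name!r} must border nonconductor "
                                f"(sigma_out = {s.sigma_out})")

    # conductivity consistency: for each surface, the conductivity just outside
    # must match sigma_in of the immediately enclosing surface's compartment
    consistent = True
    for s in model.surfaces:
        enclosing = [o for o in model.surfaces
                     if o.name != s.name and containment.get((s.name, o.name), False)]
        if enclosing:
            # nearest enclosing surface = smallest enclosed volume
            nearest = min(enclosing, key=lambda o: abs(o.mesh.signed_volume()))
            others_in_between = [o for o in enclosing if o is not nearest]  # noqa: F841
            if not np.isclose(s.sigma_out, nearest.sigma_in) and not any(
                    containment.get((o.name, nearest.name), False) and
                    containment.get((s.name, o.name), False) for o in model.surfaces
                    if o.name not in (s.name, nearest.name)):
                consistent = False
                problems.append(
                    f"sigma_out of {s.name!r} ({s.sigma_out}) does not match "
                    f"sigma_in of enclosing {nearest.name!r} ({nearest.sigma_in})")

    report = ValidationReport(closed=closed, outward=outward,
                              outermost_nonconductor=outermost_ok,
                              conductivity_consistent=consistent,
                              disjoint=disjoint, problems=tuple(problems))
    if strict and not report.ok:
        raise ValueError("head model validation failed: " + "; ".join(report.problems))
    return report
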