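"""BEM kernels, assembly, deflation, ISA and solves."""

import numpy as np
import pytest
from scipy.integrate import dblquad

from headbem import (BoundarySurface, HeadModel, assemble_geometry,
                     assemble_system, build_icosphere,
                     build_layered_sphere_model, linear_collocation_weights,
                     solid_angles, solve_potentials, source_terms,
                     transfer_matrix)
from headbem import _kernels
from headbem.headmodel import DEFAULT_MESH_LEVELS

LV2 = {k: 2 for k in DEFAULT_MESH_LEVELS}


def cube_mesh(side=2.0):
    """Closed, outward-oriented cube centered at the origin."""
    import trimesh
    m = trimesh.creation.box(extents=(side, side, side))
    from headbem import TriMesh
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces), name="cube")


class TestSolidAngles:
    def test_interior_rows_sum_to_4pi(self):
        m = build_icosphere(2, 10.0)
        pts = np.array([[0.0, 0, 0], [1.0, -2.0, 3.0]])
        rows = solid_angles(m, pts)
        assert np.allclose(rows.sum(axis=1), 4 * np.pi, atol=1e-9)

    def test_exterior_rows_sum_to_zero(self):
        m = build_icosphere(2, 10.0)
        rows = solid_angles(m, [[30.0, 0, 0], [0, 0, -15.0]])
        assert np.allclose(rows.sum(axis=1), 0.0, atol=1e-9)

    def test_on_surface_point_rejected(self):
        m = build_icosphere(1, 10.0)
        with pytest.raises(ValueError):
            solid_angles(m, m.vertices[:1])

    def test_cube_corner_octant_limit(self):
        """Approaching a cube corner from inside along the diagonal, the
        three incident faces at that corner together subtend the
        complementary angle 4*pi - 3*(pi/2)... -> their sum tends to the
        solid angle of the corner octant seen from inside: each remote
        octant contributes, so the three *adjacent* faces approach
        4*pi - pi/2 minus the far faces: checked against the straight
        limit of the total (4*pi) minus the far-face analytic values."""
        m = cube_mesh(2.0)
        corner = np.array([1.0, 1.0, 1.0])
        # faces incident to the corner
        touch = np.array([np.any(np.all(np.isclose(m.vertices[f], corner), axis=1))
                          for f in m.faces])
        for eps in (1e-3, 1e-5):
            p = corner - eps  # just inside along the diagonal
            rows = solid_angles(m, [p - 0.0])[0]
            near = rows[touch].sum()
            far = rows[~touch].sum()
            # all of 4*pi except the corner octant (pi/2) comes from the
            # three incident faces in the limit
            assert near == pytest.approx(4 * np.pi - np.pi / 2, abs=40 * eps)
            assert far == pytest.approx(np.pi / 2, abs=40 * eps)


class TestLinearWeights:
    def test_partition_of_unity_matches_solid_angles(self):
        m = build_icosphere(2, 10.0)
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((20, 3)) * 3.0
        per_face = _kernels.linear_basis_solid_angles(pts, m.triangles)
        sa = _kernels.solid_angles(pts, m.triangles)
        assert np.abs(per_face.sum(-1) - sa).max() < 1e-10

    def test_far_field_weights_vanish(self):
        m = build_icosphere(1, 10.0)
        w = linear_collocation_weights(m, [[5000.0, 0.0, 0.0]])
        assert np.abs(w).sum() < 1e-6

    def test_weights_match_adaptive_quadrature(self):
        """Independent oracle: numerically integrate the double-layer kernel
        times each hat function over a random triangle."""
        rng = np.random.default_rng(3)
        tri = rng.standard_normal((3, 3))
        p = rng.standard_normal(3) * 4.0
        w = _kernels.linear_basis_solid_angles(p[None], tri[None])[0, 0]
        nrm = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        area2 = np.linalg.norm(nrm)
        nhat = nrm / area2

        def kern(u, v, k):
            x = tri[0] + u * (tri[1] - tri[0]) + v * (tri[2] - tri[0])
            h = (1.0 - u - v, u, v)[k]
            y = x - p
            return h * (y @ nhat) / np.linalg.norm(y) ** 3 * area2

        for k in range(3):
            ref, err = dblquad(lambda v, u: kern(u, v, k), 0, 1, 0, lambda u: 1 - u,
                               epsabs=1e-12, epsrel=1e-10)
            assert w[k] == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_fast_kernel_matches_reference_kernel(self):
        from headbem import _fastkernels
        m = build_icosphere(2, 9.0)
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((30, 3)) * 4.0
        ref = _kernels.linear_basis_solid_angles(pts, m.triangles)
        fast = _fastkernels.lc_weight_rows(pts, m.triangles, m.faces, m.n_vertices)
        slow = np.zeros_like(fast)
        for k in range(3):
            np.add.at(slow, (slice(None), m.faces[:, k]), ref[..., k])
        assert np.abs(fast - slow).max() < 1e-12


class TestAssembly:
    def test_constant_vector_in_nullspace(self):
        """With the closure correction, constants solve the homogeneous
        undeflated equations exactly (both weightings)."""
        model = build_layered_sphere_model("4C", K=50.0, mesh_levels=LV2)
        for method in ("LC", "LG"):
            geo = assemble_geometry(model, method)
            from headbem.bem import _build_operator
            a = _build_operator(geo, model)
            res = np.abs(a @ np.ones(geo.n)).max()
            assert res < 1e-12 * np.abs(a).max()

    def test_lc_and_lg_systems_share_dimensions(self):
        model = build_layered_sphere_model("4C", K=50.0, mesh_levels=LV2)
        lc = assemble_system(model, "LC", use_isa=False)
        lg = assemble_system(model, "LG", use_isa=False)
        assert lc.n == lg.n == model.n_vertices
        assert np.array_equal(lc.geometry.offsets, lg.geometry.offsets)

    def test_geometry_method_mismatch_rejected(self):
        model = build_layered_sphere_model("4C", K=50.0, mesh_levels=LV2)
        geo = assemble_geometry(model, "LC")
        with pytest.raises(ValueError):
            assemble_system(model, "LG", geometry=geo)

    def test_undeflated_solve_refused(self):
        mesh = build_icosphere(1, 90.0, name="scalp")
        model = HeadModel((BoundarySurface(mesh, 0.33, 0.0),))
        sys_ = assemble_system(model, "LC", use_isa=False, deflate=False)
        with pytest.raises(RuntimeError, match="deflat"):
            solve_potentials(sys_, np.zeros((sys_.n, 1)))


@pytest.fixture(scope="module")
def system(model_l2):
    return assemble_system(model_l2, "LC", use_isa=True)


class TestSolve:
    def test_zero_sources_give_zero_potentials(self, system):
        phi = solve_potentials(system, np.zeros((system.n, 3)))
        assert np.all(phi == 0.0)

    def test_linearity_in_moment(self, system):
        pos = np.array([[0.0, 0.0, 0.05]])
        mom = np.array([[1e-8, 2e-9, 0.0]])
        s1 = source_terms(system, pos, mom)
        s3 = source_terms(system, pos, 3.0 * mom)
        phi1 = solve_potentials(system, s1)
        phi3 = solve_potentials(system, s3)
        assert np.linalg.norm(phi3 - 3.0 * phi1) <= 1e-12 * np.linalg.norm(phi3)

    def test_superposition(self, system):
        pos = np.array([[0.0, 0.0, 0.05], [0.02, -0.01, 0.03]])
        mom = np.array([[1e-8, 0, 0], [0, 1e-8, -2e-9]])
        both = solve_potentials(system, source_terms(system, pos, mom)).sum(axis=1)
        sep = sum(solve_potentials(system, source_terms(system, pos[i:i + 1],
                                                        mom[i:i + 1]))[:, 0]
                  for i in range(2))
        denom = np.linalg.norm(sep)
        assert np.linalg.norm(both - sep) <= 1e-12 * denom

    def test_dimension_mismatch_reports_vertex_count(self, system):
        with pytest.raises(ValueError, match=str(system.n)):
            solve_potentials(system, np.zeros((7, 1)))


class TestTransferMatrix:
    def test_matches_direct_solve_on_random_sources(self, model_l2):
        system = assemble_system(model_l2, "LC", use_isa=True)
        rng = np.random.default_rng(8)
        n_ch = 5
        w = rng.standard_normal((n_ch, system.n))
        t = transfer_matrix(system, w)
        pos = rng.uniform(-0.03, 0.03, (20, 3))
        mom = rng.standard_normal((20, 3)) * 1e-8
        terms = source_terms(system, pos, mom)
        direct = w @ solve_potentials(system, terms)
        via_t = t @ terms
        assert np.abs(via_t - direct).max() <= 1e-10 * np.abs(direct).max()

    def test_empty_channel_set(self, model_l2):
        system = assemble_system(model_l2, "LC", use_isa=True)
        assert transfer_matrix(system, np.zeros((0, system.n))).shape == (0, system.n)


class TestIsa:
    def test_isa_reduces_oracle_error_at_fixed_mesh(self, model_l2, sensors_l2,
                                                    small_sources):
        """Isolating the high-contrast skull must improve EEG accuracy on the
        same mesh (here at K = 50, the verification conductivity)."""
        from conftest import default_sphere_spec, oracle_eeg
        from headbem import compare_leadfields, eeg_leadfield

        electrodes, _ = sensors_l2
        ref = oracle_eeg(default_sphere_spec(), small_sources, electrodes)
        geo = assemble_geometry(model_l2, "LC")
        res = {}
        for isa in (False, True):
            system = assemble_system(model_l2, "LC", use_isa=isa, geometry=geo)
            lf = eeg_leadfield(model_l2, system, small_sources, electrodes)
            res[isa] = compare_leadfields(ref, lf.matrix).median_re
        assert res[True] < res[False]

    def test_isa_gauge_invariance(self, model_l2):
        """The ISA right-hand side is invariant to the arbitrary constant in
        the isolated potential: T applied to the all-ones vector vanishes."""
        system = assemble_system(model_l2, "LC", use_isa=True)
        t = system._iso["transform"]
        scale = np.abs(t).max()
        assert np.abs(t @ np.ones(t.shape[1])).max() < 1e-10 * scale

    def test_isa_disabled_without_inner_skull(self):
        mesh = build_icosphere(1, 90.0, name="scalp")
        model = HeadModel((BoundarySurface(mesh, 0.33, 0.0),))
        system = assemble_system(model, "LC", use_isa=True)
        assert not system.use_isa

    def test_unknown_isolation_surface_rejected(self, model_l2):
        with pytest.raises(ValueError):
            assemble_system(model_l2, "LC", use_isa=True,
                            isolation_surface="no_such_surface")
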