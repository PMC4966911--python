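"""Dipole fields, source spaces and sensor models."""

import numpy as np
import pytest

from headbem import (Dipole, build_sensor_arrays, build_source_space,
                     dipole_potential_infinite, dipole_primary_field,
                     electrode_potentials, magnetometer_readings)
from headbem.sources import MU0
from headbem._kernels import closest_point_on_triangles


class TestDipolePotential:
    def test_closed_form_value(self):
        # p = 1e-8 A*m along z, sigma = 0.33, on-axis point 10 mm away:
        # phi = p*d / (4 pi sigma d^3) = 2.412e-5 V
        d = Dipole([0, 0, 0], [0, 0, 1e-8])
        val = dipole_potential_infinite(d, [[0, 0, 0.01]], 0.33)[0]
        expected = 1e-8 * 0.01 / (4 * np.pi * 0.33 * 0.01 ** 3)
        assert val == pytest.approx(expected, rel=1e-12)
        assert val == pytest.approx(2.41e-5, rel=1e-2)

    def test_perpendicular_point_is_zero(self):
        d = Dipole([0, 0, 0], [0, 0, 1e-8])
        assert dipole_potential_infinite(d, [[0.02, 0.01, 0.0]], 0.33)[0] == 0.0

    def test_doubling_sigma_halves_potential(self):
        d = Dipole([0.001, 0, 0], [1e-8, 2e-9, 0])
        pts = [[0.02, 0.01, -0.005]]
        assert (dipole_potential_infinite(d, pts, 0.66)[0]
                == pytest.approx(dipole_potential_infinite(d, pts, 0.33)[0] / 2))

    def test_singular_point_rejected(self):
        d = Dipole([0, 0, 0.01], [0, 0, 1e-8])
        with pytest.raises(ValueError):
            dipole_potential_infinite(d, [[0, 0, 0.01]], 0.33)
        with pytest.raises(ValueError):
            dipole_potential_infinite(d, [[0, 0, 0.02]], 0.0)


class TestDipolePrimaryField:
    def test_parallel_displacement_gives_zero(self):
        d = Dipole([0, 0, 0], [0, 0, 1e-8])
        b = dipole_primary_field(d, [[0, 0, 0.05]])
        assert np.allclose(b, 0.0)

    def test_right_angle_magnitude(self):
        p, dist = 1e-8, 0.07
        d = Dipole([0, 0, 0], [0, 0, p])
        b = dipole_primary_field(d, [[dist, 0, 0]])
        assert np.linalg.norm(b) == pytest.approx(MU0 * p / (4 * np.pi * dist ** 2),
                                                  rel=1e-12)

    def test_antisymmetric_in_moment(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((5, 3)) * 0.1
        mom = rng.standard_normal(3) * 1e-8
        b_plus = dipole_primary_field(Dipole([0, 0, 0.01], mom), pts)
        b_minus = dipole_primary_field(Dipole([0, 0, 0.01], -mom), pts)
        assert np.allclose(b_plus, -b_minus)


class TestSourceSpace:
    def test_counts_and_depth_constraint(self):
        src = build_source_space(200, seed=1)
        assert len(src) == 200
        radii = np.linalg.norm(src.positions_m, axis=1) * 1000.0
        assert radii.max() <= 78.0 - 1.5 + 1e-9

    def test_deterministic_given_seed(self):
        a = build_source_space(50, seed=9)
        b = build_source_space(50, seed=9)
        c = build_source_space(50, seed=10)
        assert np.array_equal(a.positions_m, b.positions_m)
        assert np.array_equal(a.moments, b.moments)
        assert not np.array_equal(a.positions_m, c.positions_m)

    def test_radial_mode_aligns_moment_with_position(self):
        src = build_source_space(40, orientation_mode="radial", seed=2)
        cosang = np.einsum("ij,ij->i", src.positions_m, src.moments)
        cosang /= (np.linalg.norm(src.positions_m, axis=1)
                   * np.linalg.norm(src.moments, axis=1))
        assert np.allclose(cosang, 1.0, atol=1e-12)

    def test_tangential_mode_orthogonal_to_position(self):
        src = build_source_space(40, orientation_mode="tangential", seed=2)
        dots = np.einsum("ij,ij->i", src.positions_m, src.moments)
        assert np.abs(dots).max() < 1e-18

    def test_infeasible_range_rejected(self):
        with pytest.raises(ValueError):
            build_source_space(10, radius_range_mm=(60.0, 77.5))


class TestSensorArrays:
    def test_default_counts(self, model_l2, sensors_l2):
        electrodes, magnetometers = sensors_l2
        assert len(electrodes) == 256
        assert len(magnetometers) == 102

    def test_electrodes_on_scalp_surface(self, model_l2, sensors_l2):
        electrodes, _ = sensors_l2
        scalp = model_l2.surfaces[-1].mesh
        _, d, _, _ = closest_point_on_triangles(electrodes.positions_m * 1000.0,
                                                scalp.triangles)
        assert d.max() < 1e-3  # mm, i.e. 1e-6 m

    def test_magnetometer_integration_rules(self, sensors_l2):
        _, mags = sensors_l2
        assert np.allclose(mags.weights, 0.25)
        # integration points lie in the coil plane
        rel = mags.integration_points_m - mags.centers_m[:, None, :]
        out_of_plane = np.einsum("cqx,cx->cq", rel, mags.normals)
        assert np.abs(out_of_plane).max() < 1e-12
        assert np.allclose(np.linalg.norm(mags.normals, axis=1), 1.0)

    def test_too_small_helmet_rejected(self, model_l2):
        with pytest.raises(ValueError):
            build_sensor_arrays(model_l2, helmet_radius_mm=50.0)


class TestElectrodeInterpolation:
    def test_affine_field_reproduced_exactly(self, model_l2, sensors_l2):
        electrodes, _ = sensors_l2
        scalp = model_l2.surfaces[-1].mesh
        a = np.array([3.0, -2.0, 0.5])
        nodal = scalp.vertices_m @ a + 0.7
        vals = electrode_potentials(nodal[:, None], electrodes)[:, 0]
        expected = electrodes.positions_m @ a + 0.7
        assert np.abs(vals - expected).max() < 1e-12

    def test_weights_sum_to_one(self, sensors_l2):
        electrodes, _ = sensors_l2
        w = electrodes.interpolation_matrix()
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_vertex_and_centroid_cases(self, model_l2):
        from headbem.sources import ElectrodeArray
        scalp = model_l2.surfaces[-1].mesh
        tri = scalp.faces[5]
        vert_pos = scalp.vertices_m[tri[0]]
        cent_pos = scalp.vertices_m[tri].mean(axis=0)
        arr = ElectrodeArray(
            positions_m=np.array([vert_pos, cent_pos]),
            faces=np.array([5, 5]),
            bary=np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]]),
            mesh=scalp)
        nodal = np.arange(scalp.n_vertices, dtype=float)[:, None]
        vals = electrode_potentials(nodal, arr)[:, 0]
        assert vals[0] == nodal[tri[0], 0]
        assert vals[1] == pytest.approx(nodal[tri, 0].mean())


class TestMagnetometerReadings:
    def test_uniform_field_projects_on_normal(self, sensors_l2):
        _, mags = sensors_l2
        b0 = np.array([1e-13, -2e-13, 5e-13])
        field = np.broadcast_to(b0, (len(mags), 4, 3))
        out = magnetometer_readings(field, mags)
        assert np.allclose(out, mags.normals @ b0, rtol=1e-12)

    def test_zero_field_gives_zero(self, sensors_l2):
        _, mags = sensors_l2
        assert np.all(magnetometer_readings(np.zeros((len(mags), 4, 3)), mags) == 0)

    def test_four_point_rule_matches_dense_grid(self, sensors_l2):
        """2x2 Gauss integration vs a 20x20 dense average of the normal
        field of a distant dipole (within 0.1%)."""
        _, mags = sensors_l2
        dip = Dipole([0.0, 0.0, 0.05], [1e-8, 0.0, 0.0])
        field4 = dipole_primary_field(dip, mags.integration_points_m.reshape(-1, 3))
        reading4 = magnetometer_readings(field4.reshape(len(mags), 4, 3), mags)

        # dense reference over each square coil
        n_g = 20
        g = (np.arange(n_g) + 0.5) / n_g - 0.5
        uu, vv = np.meshgrid(g, g)
        ref = np.empty(len(mags))
        u_ax = mags.integration_points_m[:, 0, :] - mags.centers_m
        # reconstruct coil in-plane axes from integration points
        for c in range(len(mags)):
            n_hat = mags.normals[c]
            a = u_ax[c] - (u_ax[c] @ n_hat) * n_hat
            a /= np.linalg.norm(a)
            b = np.cross(n_hat, a)
            side = mags.coil_side_m
            pts = (mags.centers_m[c]
                   + side * uu.ravel()[:, None] * a[None]
                   + side * vv.ravel()[:, None] * b[None])
            bb = dipole_primary_field(dip, pts)
            ref[c] = (bb @ n_hat).mean()
        assert np.abs(reading4 - ref).max() <= 1e-3 * np.abs(ref).max()

    def test_dimension_mismatch_rejected(self, sensors_l2):
        _, mags = sensors_l2
        with pytest.raises(ValueError):
            magnetometer_readings(np.zeros((3, 4, 3)), mags)
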