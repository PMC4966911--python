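"""Shared fixtures.

The expensive objects (BEM geometries, the multi-resolution oracle
comparison, the compensation study) are session-scoped and shared between
unit and acceptance tests; everything is generated programmatically from
seeds, so the suite needs no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from headbem import (SphereStudyGeometry, assemble_system,
                     build_layered_sphere_model, build_sensor_arrays,
                     build_source_space, compare_leadfields, eeg_leadfield,
                     meg_leadfield, multilayer_sphere_potential, sarvas_field)
from headbem.sphere import LayeredSphereSpec

ALL_SURFACES = ("pial", "inner_skull", "outer_skull", "scalp")


def uniform_levels(level: int) -> dict:
    return {name: level for name in ALL_SURFACES}


def default_sphere_spec(K: float = 50.0) -> LayeredSphereSpec:
    return LayeredSphereSpec((0.078, 0.081, 0.087, 0.092),
                             (0.33, 1.79, 0.33 / K, 0.33))


@pytest.fixture(scope="session")
def model_l2():
    return build_layered_sphere_model("4C", K=50.0, mesh_levels=uniform_levels(2))


@pytest.fixture(scope="session")
def small_sources():
    return build_source_space(12, radius_range_mm=(50.0, 72.0), seed=4)


@pytest.fixture(scope="session")
def sensors_l2(model_l2):
    return build_sensor_arrays(model_l2)


def oracle_eeg(spec, sources, electrodes):
    """Analytic average-referenced electrode potentials (channels x sources)."""
    out = np.stack([multilayer_sphere_potential(spec, p, m, electrodes.positions_m)
                    for p, m in zip(sources.positions_m, sources.moments)], axis=1)
    return out - out.mean(axis=0)


def oracle_meg(sources, magnetometers):
    """Sarvas coil readings (channels x sources) for a centered sphere."""
    flat = magnetometers.integration_points_m.reshape(-1, 3)
    out = np.empty((len(magnetometers), len(sources)))
    for j in range(len(sources)):
        b = sarvas_field(sources.positions_m[j], sources.moments[j], flat)
        b = b.reshape(len(magnetometers), 4, 3)
        out[:, j] = np.einsum("cqx,cx,q->c", b, magnetometers.normals,
                              magnetometers.weights)
    return out


@pytest.fixture(scope="session")
def convergence_table():
    """Median RE vs the analytic oracles over icosphere levels 2-4 for both
    weightings and both modalities (the multi-resolution verification), plus
    the level-4 radial/tangential MEG suppression ratio.

    200 dipoles at depths 1.5-20 mm below the pial surface, random
    orientations; EEG compared at 256 surrogate electrodes, MEG at 102
    surrogate magnetometers.
    """
    import gc

    sources = build_source_space(200, seed=0)
    spec = default_sphere_spec()
    table = {}
    extras = {}
    for level in (2, 3, 4):
        model = build_layered_sphere_model("4C", K=50.0, mesh_levels=uniform_levels(level))
        electrodes, magnetometers = build_sensor_arrays(model)
        ref_eeg = oracle_eeg(spec, sources, electrodes)
        ref_meg = oracle_meg(sources, magnetometers)
        for method in ("LC", "LG"):
            # the level-4 operators are ~GB-scale; release each system fully
            # before assembling the next
            system = None
            gc.collect()
            system = assemble_system(model, method, use_isa=True)
            lf_eeg = eeg_leadfield(model, system, sources, electrodes)
            lf_meg = meg_leadfield(model, system, sources, magnetometers)
            table[(level, method, "EEG")] = compare_leadfields(ref_eeg, lf_eeg.matrix)
            table[(level, method, "MEG")] = compare_leadfields(ref_meg, lf_meg.matrix)
            if level == 4 and method == "LC":
                dirs = sources.positions_m / np.linalg.norm(sources.positions_m,
                                                            axis=1)[:, None]
                rad = type(sources)(sources.positions_m, dirs * 1e-8)
                tan_m = np.cross(dirs, sources.moments)
                tan_m /= np.linalg.norm(tan_m, axis=1)[:, None]
                tan = type(sources)(sources.positions_m, tan_m * 1e-8)
                lr = meg_leadfield(model, system, rad, magnetometers).matrix
                lt = meg_leadfield(model, system, tan, magnetometers).matrix
                extras["radial_tangential_ratio"] = (
                    np.linalg.norm(lr, axis=0) / np.linalg.norm(lt, axis=0))
            system = None
            gc.collect()
    return {"table": table, "extras": extras}


@pytest.fixture(scope="session")
def compensation_study():
    """The scaled-down EEG compensation study on the default sphere surrogate
    (level-3 meshes, 200 sources, 256 electrodes, Galerkin reference and
    test solvers, K_ref 20:10:80 vs K_test 20:10:170)."""
    from headbem import conductivity_sweep, select_optimal_K

    study = SphereStudyGeometry.build(n_sources=200, seed=0)
    k_ref = np.arange(20.0, 81.0, 10.0)
    k_test = np.arange(20.0, 171.0, 10.0)
    sweep_3s = conductivity_sweep(study, "EEG", k_ref_grid=k_ref, k_test_grid=k_test,
                                  test_kind="3S", method="LG")
    sweep_4c = conductivity_sweep(study, "EEG", k_ref_grid=k_ref, k_test_grid=k_ref,
                                  test_kind="4C", method="LG")
    sel_3s = select_optimal_K(sweep_3s)
    sel_4c = select_optimal_K(sweep_4c)
    mean_re = sweep_3s.mean_re()
    diag = [int(np.where(k_test == k)[0][0]) for k in k_ref]
    uncompensated = float(np.mean([mean_re[i, j] for i, j in enumerate(diag)]))
    j_equi = int(np.where(k_test == sel_3s["K_best"])[0][0])
    compensated = float(mean_re[:, j_equi].mean())
    return {"study": study, "sweep_3s": sweep_3s, "sweep_4c": sweep_4c,
            "sel_3s": sel_3s, "sel_4c": sel_4c,
            "k_ref": k_ref, "k_test": k_test,
            "uncompensated_mean_re": uncompensated,
            "compensated_mean_re": compensated}


@pytest.fixture(scope="session")
def meg_perturbed_sweep():
    """MEG K-robustness on the 5%-perturbed sphere surrogate."""
    from headbem import conductivity_sweep

    study = SphereStudyGeometry.build(n_sources=200, seed=0,
                                      perturbation_amplitude=0.05,
                                      perturbation_seed=11)
    kk = np.arange(20.0, 81.0, 10.0)
    return conductivity_sweep(study, "MEG", k_ref_grid=kk, k_test_grid=kk,
                              test_kind="4C", method="LC", ref_method="LC")
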