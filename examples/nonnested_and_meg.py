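"""Non-nested head models and the MEG volume-current term.

Two demonstrations on synthetic geometry:

1. a non-nested five-sub-volume model (4-C spheres plus two disjoint
   brain-conductivity blobs floating in CSF-labelled space) passes
   validation and solves like any other model — only per-surface
   conductivity jumps matter, no containment tree is needed;
2. a boundary whose inside and outside conductivities match (zero jump) is
   electromagnetically inert: adding it changes neither EEG nor MEG.
"""

import numpy as np

from headbem import (BoundarySurface, HeadModel, assemble_system,
                     build_icosphere, build_layered_sphere_model,
                     build_nonnested_test_model, build_sensor_arrays,
                     build_source_space, meg_leadfield, validate_model)

lv = {k: 2 for k in ("pial", "inner_skull", "outer_skull", "scalp")}

nonnested = build_nonnested_test_model(K=50.0, mesh_levels=lv)
report = validate_model(nonnested)
print(f"non-nested model: {nonnested.labels}")
print(f"validation passed: {report.ok} (closed, outward, disjoint, consistent)")
src = build_source_space(4, radius_range_mm=(15.0, 30.0), seed=1,
                         brain_radius_mm=40.0)
_, mags = build_sensor_arrays(nonnested)
lf = meg_leadfield(nonnested, assemble_system(nonnested, "LC"), src, mags)
print(f"MEG leadfield on the non-nested model: {lf.matrix.shape}, "
      f"max |B| = {np.abs(lf.matrix).max():.3e} T")

base = build_layered_sphere_model("4C", K=50.0, mesh_levels=lv)
ghost = BoundarySurface(build_icosphere(2, 89.5, name="ghost"), 0.33, 0.33)
padded = HeadModel(tuple(base.surfaces) + (ghost,), K=base.K)
src = build_source_space(4, radius_range_mm=(55.0, 70.0), seed=1)
_, mags = build_sensor_arrays(base)
lf_a = meg_leadfield(base, assemble_system(base, "LC"), src, mags).matrix
lf_b = meg_leadfield(padded, assemble_system(padded, "LC"), src, mags).matrix
rel = np.linalg.norm(lf_a - lf_b) / np.linalg.norm(lf_a)
print(f"\nzero-jump ghost surface added: relative leadfield change {rel:.2e}")
print("(the coupling of every boundary scales with its conductivity jump,")
print(" so an equal-conductivity boundary contributes nothing)")
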