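# headbem

Surface-based boundary-element (BEM) forward modeling for MEG/EEG with
four-compartment head models that include cerebrospinal fluid (CSF), and a
principled way to *compensate* for CSF when it is left out of a simpler
three-shell model.

## Who this is for

Researchers building MEG/EEG forward models: the package solves the quasi-static
potential equation for piecewise-homogeneous volume conductors described by
closed triangle meshes, computes electrode potentials and magnetometer
readings for current-dipole sources, and quantifies how model simplifications
(omitting CSF, mis-specifying skull conductivity, coarse meshing) distort
signal topographies. All experiments run on built-in synthetic geometry
(layered spheres, perturbed spheres, non-nested multi-sphere models); no MRI
data or external meshes are required, though OFF/STL/PLY meshes can be loaded.

## The model

The electric potential φ on the conductivity boundaries S_l obeys

    2π(σ⁻ + σ⁺) φ(r) = 4π σ₀ φ∞(r) + Σ_l (σ⁻_l − σ⁺_l) PV ∫_{S_l} φ dΩ_r ,

where φ∞ is the infinite-medium potential of the primary current, dΩ_r the
solid-angle measure seen from r, and σ⁻/σ⁺ the conductivities inside/outside
each boundary. φ is discretized with linear (hat) basis functions and the
residual weighted pointwise at vertices (**linear collocation, LC**) or with
the hat functions themselves (**linear Galerkin, LG**). The double-layer
integrals use de Munck's analytic closed form; the constant null space is
removed by deflation; the **isolated source approach (ISA)** splits off the
sub-problem inside the poorly conducting skull to suppress numerical error
amplification. The magnetic field follows from the Geselowitz equation

    B(r) = B∞(r) − (μ0/4π) Σ_l (σ⁻_l − σ⁺_l) ∫_{S_l} φ dS′ × (r−r′)/|r−r′|³ .

Compartments: brain and scalp 0.33 S/m, CSF 1.79 S/m, skull 0.33/K, with K
the soft-tissue-to-skull resistivity ratio (literature range ≈ 20–80).
Topographies are compared per source with the relative error
RE = |d_ref − d_test| / |d_ref| and the centered correlation CC.
Analytic references (multilayer-sphere series; the Sarvas field) make
verification self-contained.

## Worked example

```bash
python examples/forward_sphere.py
```

```
model: 4C, K = 50.0, 2568 boundary vertices
EEG leadfield: (256, 5), MEG leadfield: (102, 5)
source 0: depth   6.4 mm   |EEG| = 6.604e-06 V   |MEG| = 4.621e-13 T
source 1: depth  11.4 mm   |EEG| = 5.624e-06 V   |MEG| = 3.218e-13 T
...
```

The numbers are root-sum-square topography amplitudes for 10 nA·m dipoles:
microvolt-scale EEG at 256 average-referenced electrodes and sub-picotesla
MEG at 102 magnetometers, decaying with source depth.

`examples/compensation_mini_study.py` shows the core scientific result in
miniature: when the CSF is omitted, the best three-shell skull ratio K_test
is about 2–2.5× the true ratio K_ref, i.e. the skull conductivity should be
*lowered* to stand in for the missing high-conductivity CSF layer:

```
K_ref  20:  best K_test = 50  (factor 2.50)
K_ref  50:  best K_test = 110 (factor 2.20)
K_ref  80:  best K_test = 140 (factor 1.75)
```

Other entry points: `examples/verify_against_oracle.py` (convergence against
the analytic sphere series), `examples/nonnested_and_meg.py` (non-nested
five-sub-volume models; inertness of zero-jump boundaries), and the
config-driven CLI:

```bash
headbem verify-sphere config.yaml   # oracle verification report
headbem forward config.yaml        # leadfields for one model
headbem sweep config.yaml          # (K_ref, K_test) metric matrix
headbem study config.yaml          # full compensation study
```

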