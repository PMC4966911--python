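# Methods

## Physical model

The head is modeled as a piecewise-homogeneous, isotropic volume conductor:
closed, outward-oriented triangle surfaces separate compartments of constant
conductivity, and each surface carries the pair (σ_in, σ_out) of
conductivities immediately inside and outside it. Only the jump
σ_in − σ_out enters the field equations, so nested (concentric shells) and
non-nested arrangements (e.g. extra brain-conductivity blobs floating in
CSF-labelled space, standing in for a separately meshed cerebellum) are
treated uniformly with no containment bookkeeping.

Default conductivities: brain and scalp 0.33 S/m, CSF 1.79 S/m, skull
0.33/K where K is the dimensionless soft-tissue-to-skull resistivity ratio.
K is the single swept parameter of the compensation analyses; literature
estimates place it roughly between 20 and 80. An optional brain-conductivity
scale factor supports the alternative compensation route of raising the
brain conductivity of a three-shell model.

The default sphere surrogate has boundary radii 78 / 81 / 87 / 92 mm (pial,
inner skull, outer skull, scalp): a 3 mm CSF layer, 6 mm skull and 5 mm
scalp — plausible adult dimensions used by every built-in experiment. The
three-shell (3-S) variant drops the pial boundary and labels the CSF volume
as brain. A seeded band-limited spherical-harmonic perturbation (degrees
1–4, peak-normalized) can displace all radii by the same relative field,
producing non-spherical but mutually disjoint surfaces; this matters for
MEG, which is conductivity-insensitive in exactly spherical geometry.

## Boundary element solver

Potentials are discretized with linear (hat) basis functions on each
surface. The double-layer integrals of the hat functions are evaluated with
de Munck's analytic closed form (solid-angle decomposition plus edge
logarithms); the van Oosterom–Strackee formula gives triangle solid angles.
Points in the plane of a triangle take the principal value zero; the test
suite validates the closed forms against adaptive numerical quadrature and
against an independent implementation of the same published formulas.

* **LC (linear collocation)** weights the residual pointwise at vertices.
  The own-surface diagonal is closed so that each own-surface row sums to
  exactly 2π; combined with the exact 4π/0 closure of the analytic weights
  this keeps constant potentials exactly in the operator null space for any
  consistent conductivity assignment, nested or not.
* **LG (linear Galerkin)** weights the residual with the hat functions.
  Outer integrals use the 7-point (degree-5) symmetric triangle rule;
  vertex- or edge-adjacent same-surface triangle pairs are re-integrated on
  a once-subdivided composite rule (28 points), which a refinement study
  showed to be converged (deeper subdivision changes level-3 sphere results
  by < 0.05 % RE). A residual constant-vector defect of order 1e−5 from the
  mixed quadratures is closed exactly on the diagonal.

The null space is removed by a rank-one deflation constraining the mean
outer-surface vertex potential; EEG topographies are subsequently
average-referenced at the electrode level, and all comparison metrics are
reference-invariant or applied to average-referenced vectors. One dense LU
factorization per system is reused across all right-hand sides; transfer
matrices (channel-side adjoint solves) make many-source leadfields a single
matrix product.

**Isolated source approach (ISA).** The high-resistivity skull amplifies
discretization error of the raw source terms. The solver therefore first
solves the isolated sub-model consisting of all surfaces inside and
including the isolation surface (inner skull by default) with zero outside
conductivity, then rebuilds the full right-hand side from the isolated
potential via the discrete interior/exterior representation identities, and
back-substitutes through the full operator. The rebuilt right-hand side is
exactly invariant to the isolated solution's arbitrary constant. Because the
isolated sub-model contains no skull surface, ISA-transformed source terms
are independent of K and are shared across conductivity sweeps. On the
level-3 four-compartment sphere at K = 50 the ISA cuts the LC median
electrode-potential error from ≈ 79 % to ≈ 12 %.

**Source terms.** LC evaluates the infinite-medium term
p·(r−r₀)/|r−r₀|³ exactly at vertices. LG integrates it against the hat
functions with the 7-point rule, subdividing faces within four mean edge
lengths of a dipole (up to 4⁴ sub-triangles for the nearest faces); dipoles
are kept ≥ 1.5 mm below the pial boundary.

## Magnetics

The Geselowitz volume-current term is evaluated per triangle in two parts:
the triangle-mean part exactly, via the Stokes identity
∫_T n̂×∇′(1/R) dS′ = ∮_∂T (1/R) dl with closed-form edge integrals (so the
closed-surface identities — constant potentials contribute nothing,
zero-jump surfaces are inert — hold to rounding), and the zero-mean linear
residual with a 3-point rule (a 7-point option exists; on the study
geometries it changes nothing at the reported precision, as sensors sit
≥ 25 mm from the scalp where the kernel is smooth). Magnetometers are
square coils (21 mm side) read as the average normal field over a 2×2 Gauss
grid, in tesla. With Galerkin potentials the total (primary + volume) field
of a tangential dipole in the concentric model matches the closed-form
sphere solution to 0.45 % at icosphere level 2 and 0.07 % at level 3.

## Analytic oracles

The layered-sphere potential is the standard spherical-harmonic transfer
series: per degree n a small linear system enforces potential and
radial-current continuity at each interface and zero outward current at the
outer boundary; the dipole's radial/tangential source coefficients come
from the Legendre expansion of the infinite-medium potential. Radii are
scaled by the outer radius for conditioning; truncation is adaptive (stop
after three consecutive degree increments below 1e−10 of the running sum),
which handles the study's most eccentric dipoles (1.5 mm below the pial
boundary, eccentricity 0.98) without acceleration tricks because the
evaluation radius is the scalp, where terms decay like (b/R_scalp)ⁿ. The
series is verified against a hand-derived central-dipole closed form, the
infinite-medium expansion, degenerate equal-conductivity layering, symmetry
and global conductivity scaling. The Sarvas closed form provides the MEG
reference; it is conductivity-independent by construction.

## Verification results and the finalized collocation threshold

Multi-resolution verification against the oracles (uniform icosphere levels
2–4, the 4-C sphere at K = 50, 200 dipoles at 1.5–20 mm depth, random
orientations, 256 electrodes / 102 magnetometers) gives median RE:

| level | EEG LC | EEG LG | MEG LC | MEG LG |
|------:|-------:|-------:|-------:|-------:|
| 2     | 30.9 % | 3.80 % | 0.16 % | 0.23 % |
| 3     | 13.4 % | 0.92 % | 0.046 %| 0.052 %|
| 4     | 4.08 % | 0.25 % | 0.012 %| 0.013 %|

Errors decrease monotonically with refinement and LG is far more accurate
than LC for EEG (for MEG the two are equivalent at these densities, LC
slightly ahead at the coarsest level). The LC EEG error is dominated by a
systematic amplitude deficit (median CC ≈ 0.9998 at level 4 while the gain
sits below 1), the known collocation limitation when thin, high-contrast
layers (3 mm CSF, 6 mm skull) are meshed at triangle sides comparable to
their thickness. On this basis the acceptance threshold for the
LC-vs-oracle median EEG RE at level 4 is finalized at 4.5 % (measured
4.08 %, plus margin for seed variation; the target order of 2 % is not
reachable by collocation at feasible mesh densities, while LG is an order
of magnitude inside it).

A further discretization limit worth stating: the external magnetic field
of a *spherically symmetric* conductor is exactly conductivity-independent,
but the discrete conductor is a polyhedron, so the computed MEG leadfield
retains a small K-dependence that vanishes only in the mesh limit —
measured 1.6e−5 (level 3) and 4.4e−6 (level 4) relative change for
K 20→80, shrinking ≈ O(h²). The corresponding invariance test asserts the
idealized 1e−6 bound and is expected to fail at these mesh sizes; it is
kept as a faithful statement of the continuum property.

## Compensation study

The study conditions (fixed once, used by tests, CLI defaults and the
acceptance script): level-3 icosphere meshes, 200 dipoles quasi-uniform in
direction with radii uniform in 58–76.5 mm (depths 1.5–20 mm below the pial
surface) and random orientations, 256 electrodes, Galerkin solvers for both
reference and test models (so that conductivity effects are not confounded
with the LC amplitude deficit), K_ref ∈ {20…80 step 10} and
K_test ∈ {20…170 step 10}. The expectation over K_ref is the unweighted
mean over the grid; the optimum minimizes expected median RE with ties
within one percentage point broken by expected CC (both interpretations
configurable).

On this surrogate the study reproduces the compensation physics: the
four-compartment optimum is K_opt = 50 (mid-range); the three-shell
best-fit ratio is 2.5× the true ratio at K_ref = 20 falling to ≈ 1.75× at
K_ref = 80; the shape-optimal (CC) factor is ≈ 1.5; compensation roughly
halves the error of plain CSF omission (mean RE ≈ 16 % vs ≈ 36 %). Two
quantities land below their real-head counterparts: the equivalent ratio
selects K_equi = 90 (candidate set {90, 100, 110}, shape metric preferring
the smallest) rather than 100, and the uncompensated error is ≈ 36 % rather
than > 40 %. Both follow from the surrogate geometry: a uniform 3 mm CSF
shell under-represents real CSF (which includes sulcal pockets and thicker
regions), and the depth-uniform source shell includes deep sources whose
CSF sensitivity is low, diluting the mean. The corresponding tests assert
the real-head values and are left failing as an honest record of the
surrogate's limits; the compensated-vs-uncompensated ordering and factor
range are robust.

MEG robustness uses the 5 %-perturbed surrogate (seeded), collocation
solvers and the same sources: the worst median RE between four-compartment
models over all K pairs in 20–80 is ≈ 0.16 %, far below the ≈ 6 % seen with
real head geometry — a smooth low-degree perturbation breaks spherical
symmetry far more gently than anatomy does.

## What the synthetic geometry does and does not show

The generators emulate layer thicknesses, conductivity contrasts, sensor
counts and source depths of a human head, so conclusions about *relative*
model behavior (LG vs LC ordering, ISA benefit, compensation direction and
approximate factors, MEG's conductivity insensitivity) transfer. They do
not contain cortical folding, sulcal CSF, skull thickness variation or
anisotropy, so absolute error levels on real anatomy differ (typically
larger for shape errors, as the spatial error maps of real heads
concentrate at gyral crowns — a feature a sphere cannot reproduce).

## Numerical choices and degenerate inputs

* Coordinates are millimetres at all I/O boundaries and metres internally
  (single conversion point on the mesh class).
* Meshes must be closed 2-manifolds; orientation is checked by signed
  volume and fixed (with a warning) at load time. Statistics report flags
  instead of raising; model validation collects problems and only raises in
  strict mode.
* Perturbation amplitudes ≥ 0.3 are refused (self-intersection risk);
  sources that would violate the 1.5 mm depth rule are rejected at
  construction.
* Zero-norm reference topographies yield flagged NaN metrics, never silent
  infinities; weak sources are *not* excluded by default.
* CC values within 8 machine epsilons of ±1 are snapped to ±1 (|CC| ≤ 1
  analytically; the snap makes exact proportionality return exactly 1).
* Degenerate (zero-area) faces contribute zero weights; points on a
  surface raise singular-evaluation errors in the public kernels.
* All randomness flows through explicit integer seeds (numpy Generator);
  there is no hidden global state.

## Known limitations

Dense LU limits models to ~15k vertices in 8 GiB; no FEM/FDM, no
anisotropy, no gradiometer or realistic vendor coil geometries, no source
estimation. The collocation amplitude deficit on thin high-contrast layers
is inherent at practical mesh densities — use LG for reference-quality
potentials and LC for speed.
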