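# Methods

This note records the model, the numerical choices, and what the synthetic
phantoms do and do not establish.

## Model

The package computes structural properties of a whole small bone under
uniaxial compression with linear, small-strain, isotropic elasticity.
A segmented microCT volume is converted element-for-voxel into 8-node
trilinear hexahedra (HEX8); alternatively a 10-node quadratic tetrahedral
mesh (TET10), either externally generated or obtained by a conforming
6-tet subdivision of the voxel mesh, is used on the same geometry. The
distal (minimum-z) surface nodes are fixed in all three directions; every
proximal (maximum-z) node receives a prescribed axial displacement Δu
(default 0.1 mm) with free transverse components. Apparent stiffness is

    S = |Σ F_z over the fixed surface| / Δu        [N/mm]

Failure load uses a Pistoia-type criterion: since the model is linear, the
solution scales exactly, and the structure is deemed failed when a set
fraction of the nodes (default 10%) reaches a critical compressive third
principal strain (default −14 420 µε):

    λ = ε_crit / ε3_(r),  r = max(1, ⌊f·N⌋),  Fu = λ·|Σ F_z,fixed|

with nodal ε3 sorted ascending (most compressive first). The rank rule
⌊f·N⌋ (never below 1) is a deterministic reading of "f of the nodes
reach the critical strain"; it makes Fu continuous in f down to the
single-node limit. By construction Fu is invariant to the magnitude of Δu.

Normalized outcomes divide S and Fu by the total bone mineral content
BMC = Σ_bone TMD·V_voxel (mg), computed on the unfiltered TMD image
restricted to the segmentation mask (a flag allows computing it on the
filtered image instead; filtering redistributes but nearly conserves mass,
so the difference is far below scanner calibration uncertainty).

## Material models

Three schemes, chosen per run:

* **homo** — one modulus for all elements, default E = 14.8 GPa, ν = 0.3
  (a nanoindentation-scale cortical value for the mouse tibia).
* **homoTMD** — one specimen-specific modulus E = law(mean TMD over bone
  voxels).
* **hete** — per-element modulus from the linear TMD→E law
  E[MPa] = 10.7692·TMD + 3615.4, i.e. the line through
  (500 mgHA/cc, 9 GPa) and (1800 mgHA/cc, 23 GPa). TMD is clamped to
  [500, 1800] mgHA/cc, binned into 450 equal intervals, and each element
  receives E at its **bin center**; hex elements take their source voxel's
  TMD, voxel-derived tets inherit the parent voxel's value, and free-form
  tets average the masked voxel centers they contain (nearest-voxel
  fallback within 2 voxel spacings). The bin-center representative and the
  clamping rule are our choices — the binned law then deviates from the
  unbinned one by at most slope·binwidth/2 ≈ 15.6 MPa, and a constant-TMD
  volume reproduces the homogeneous model exactly (this equivalence is
  asserted to 1e-10 in the tests). All endpoints, the bin count and ν are
  configuration, so modulus-sweep studies are re-runnable.

The attenuation→TMD calibration is deliberately **not** defaulted: the
coefficients are scanner- and service-date-specific, so every entry point
requires them.

## Image chain

* **Plane fit / alignment.** The support-surface points are fitted by total
  least squares (SVD; normal = smallest-variance direction, oriented to
  non-negative z). The volume is rotated by the rotation taking that
  normal to +z about axis n×z, pivoting at the volume center, and
  resampled on the original grid with a separable Lanczos-3 kernel whose
  6×6×6 weights are renormalized to sum to one. The truncated sinc loses
  the partition of unity (≈0.4% ripple on a constant field); the
  renormalization restores it, so constants are preserved exactly and grid
  points reproduce exactly (an already-horizontal plane is a no-op).
  Out-of-domain samples are filled with the image's background mode; edge
  support is replicated.
* **Denoising.** 3×3×3 *sampled* Gaussian, σ = 0.65 voxels, normalized to
  unit sum, reflect padding. With this support the sampled/integrated
  kernel difference is below scanner noise; sampling is trivially
  verifiable (the impulse response *is* the kernel). σ is interpreted in
  voxels, the convention of the in vivo protocol this mirrors.
* **Threshold.** 256 bins between image min and max, 5-bin moving-average
  smoothing, local maxima at least 10 bins apart, the two most populous
  retained; threshold = exact midpoint of the two peak grey levels. A
  valley check (the smoothed histogram must dip below 50% of the lower
  peak between the two candidates) rejects unimodal histograms — flank
  noise of a single mode can otherwise masquerade as a second peak — with
  an error instructing the user to pass a manual threshold. Bin count,
  smoothing window, separation and the ≥ comparison (threshold value is
  bone) are all explicit parameters.
* **Connectivity.** Largest face-connected (6-neighborhood) component
  only; ties go to the component containing the lowest linear voxel index.
  Isolated fragments cannot carry load and would make the stiffness matrix
  singular.

## Solver numerics

* HEX8: 2×2×2 Gauss integration; the element matrix is computed once per
  (ν, edge) and scaled by each element's E. TET10: 4-point degree-2 Gauss
  rule — exact for the quadratic stiffness integrand of straight-sided
  tets, so both elements pass the linear patch test to machine precision.
* Assembly is vectorized COO→CSR with deterministic ordering (tet element
  matrices in chunks of 20 000 to bound memory).
* The constrained system K_ff u_f = −K_fc u_c is solved directly (SuperLU)
  up to 30 000 free DOFs and by Jacobi-preconditioned conjugate gradients
  (relative residual 1e-8, zero initial guess) above. We measured the
  sparse LU at ≈26× the CG wall time on a 131k-DOF tube model in this
  stack, and diagonal-scaled CG on connectivity-filtered voxel models
  converges in O(10²–10³) iterations, so the crossover favors CG early.
  Both paths are deterministic; they agree to 1e-6 on a 10³-voxel block in
  the tests.
* Reactions are K·u at constrained DOFs. Element strains are evaluated at
  centroids (B·u_e); nodal strain tensors are volume-weighted means over
  incident elements; principal strains are eigenvalues of the nodal tensor
  (e1 ≥ e2 ≥ e3). Centroid-plus-averaging is the simplest deterministic
  nodal-strain definition; the failure criterion counts **all** nodes,
  including those on the boundary-condition surfaces (`exclude_bc_nodes`
  can be emulated by masking the nodal arrays — the choice is visible, not
  buried).
* Plane membership for boundary conditions uses a strict half-plane-gap
  tolerance (half the voxel spacing for hex meshes, half the smallest
  z-plane gap for tets), so only the end planes are captured.

## Phantoms: what they emulate and what they do not

The generator produces a hollow mineralized tube (or solid prism) with a
constant or radially graded TMD field, mapped to grey levels by a linear
law plus seeded Gaussian noise, voxelized by voxel-center membership with
no anti-aliasing. That gives unambiguous ground truth (exact mask, exact
TMD, analytic bar-theory stiffness E·A/L for ν = 0) at the cost of
realism: no cortical porosity, no trabecular compartment, no curved tibial
geometry, no beam hardening or ring artifacts, and a noise model without
the correlated texture of reconstructed CT. Passing tests therefore
establish the correctness of the *mechanics and the chain's bookkeeping*
— meshing, assembly, boundary conditions, strain recovery, criterion
arithmetic, determinism — not the biological accuracy of predictions on
real tibiae, which in vivo validation studies address with paired
experimental data (those experimental tables enter through the `stats`
module as plain numbers).

Default phantom sizes keep hex models at ≈10²–10⁵ elements so the whole
suite runs on one desktop CPU; the voxel size (10.4 µm), applied
displacement (0.1 mm), failure criterion (10%, −14 420 µε) and material
constants are the study conditions themselves, not tuning knobs. A
real-scale tibia model (8–9 M hexahedra) uses the same code paths but is
an HPC-class problem and no desktop performance is claimed for it.

## Validation statistics

Predicted values (y) are regressed on experimental values (x) — the
orientation matters for slope/intercept and matches the usual
predictions-vs-measurements plots. R² = 1 − SSE/SST; RMSE uses an *n*
denominator (stated here because conventions differ); percentage errors
are |pred−exp|/exp·100 reported as mean ± sample SD (n−1); slope-vs-1 and
intercept-vs-0 use two-tailed Student t with n−2 degrees of freedom and
α = 0.05. `compare_models` additionally regresses every model's
predictions against a chosen reference model (e.g. the hexahedral
homogeneous variant) to quantify inter-model consistency.

## Known limitations

* Linear kinematics and materials only: no damage, contact, or
  embedding-compliance modelling; Fu is a linear extrapolation, which is
  the point of the criterion but also its limit.
* Tet mesh *generation* is out of scope; external C3D10/VTK meshes are
  ingested, and the 6-tet subdivision exists to exercise the TET10 solver
  on voxel geometry, not to emulate smooth-boundary meshes.
* The histogram threshold assumes a bimodal grey distribution; heavily
  osteopenic or low-dose scans may need a manual threshold.
* `crop_voi` removes ⌊frac·N_z⌋ slices per end (conservative, deterministic
  floor rule).
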