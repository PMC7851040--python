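# Methods

`cedsim` models convection-enhanced delivery (CED): direct infusion of a
drug solution into brain parenchyma through a catheter, bypassing the
blood-brain barrier. The package covers the full chain from diffusion-MRI
products to infusion predictions: microstructure-informed transport tensors,
a microscale permeability homogenization, a voxel-grid flow/transport
solver, and the shape metrics used to compare tissue models.

## Tissue model

The brain is treated as a **rigid porous medium** — the solid phase
(neurons, glia, axons) does not deform during infusion. This is justified at
low infusion rates (order 3 uL/min through a 1 mm catheter), where reported
strains are below ~2% near the tip; the payoff is a linear, cheap flow
problem. The governing equations are

    div v = 0                        (continuity, outside the source)
    v = -(K / mu) grad p             (Darcy)
    dc/dt = -div(v c) + div(D grad c) - lambda c

with `v` the superficial fluid velocity, `K` the hydraulic permeability
tensor, `D` the drug diffusivity tensor and `lambda` a first-order loss rate
lumping absorption and washout. All physics is SI; image geometry stays in
NIfTI millimetre space until the solver boundary.

Voxels are labelled by thresholds on imaging maps: CSF where the NODDI
free-water fraction exceeds 0.99, otherwise white matter (WM) where
FA > 0.23, otherwise grey matter (GM). The CSF test runs first — free fluid
can have arbitrarily low FA, so FA is only meaningful for parenchyma; FA
exactly at the threshold goes to GM (lower interval closed at the top).

Per-voxel tensors:

* **GM**: isotropic. `D_GM = D0 I` with D0 = 1.54e-10 m^2/s (gadolinium
  molecular diffusivity), `K_GM = K0 I` with K0 = 4.22e-18 m^2.
* **WM diffusivity**: the water diffusion tensor from DTI is rescaled by
  `D0 / mean(eigenvalues)`, preserving shape and orientation while pinning
  `trace(D_WM) = 3 D0` exactly — DTI supplies anisotropy, the drug's
  molecular diffusivity supplies magnitude.
* **WM permeability**: transversely isotropic,
  `K_WM = E diag(k_par, k_perp, k_perp) E^T`, principal axis along the
  leading diffusion eigenvector. The baseline ("DTI") model uses fixed
  k_par = 6.75e-15 m^2, k_perp = 4.22e-16 m^2 everywhere; the
  microstructure-aware ("DTI-NODDI") model evaluates closed-form laws in
  the extracellular volume fraction per voxel (below).
* **CSF**: no transport constants are established for free fluid in this
  framework; the package exposes configurable isotropic defaults
  (D_csf = D0, K_csf = 1e-13 m^2) and the simulator warns whenever the
  infusion volume reaches a CSF voxel. Validation phantoms confine the
  infusion to WM.

NODDI fractions are reparameterized multiplicatively: the toolbox's
intraneurite fraction is relative to the non-free-water tissue compartment,
so `vf_inc = ficvf (1 - fiso)`, `vf_enc = (1 - ficvf)(1 - fiso)`,
guaranteeing the three compartments sum to 1 per voxel; the extracellular
space fraction is `vf_ecs = vf_enc + vf_water`, the space a drug can
actually flow through. Eigendecomposition floors eigenvalues at 1e-12 (SI)
so downstream solvers always see SPD tensors, and fixes eigenvector signs
(first nonzero component positive) for reproducible tensor assembly.

## Microscale permeability laws

WM axons are idealized as parallel rigid cylinders of radius r = 0.34 um on
a triangular lattice; the extracellular space is the fluid domain. The
lattice spacing `a = r sqrt(2 pi / (sqrt(3)(1 - vf_ecs)))` sweeps VF_ECS
over [0.15, 0.80] (geometrically feasible above 1 - pi/(2 sqrt 3) ~ 0.093),
sampled more densely in the physiological 0.15-0.40 band.

Two creeping-flow problems per geometry, both solved dimensionlessly (unit
pitch, viscosity, pressure gradient; Stokes linearity restores dimensions):

* **Axial** — fully developed unidirectional flow reduces exactly to a 2-D
  Poisson problem for the axial velocity on the cell cross-section, solved
  on the quarter cell with symmetry (Neumann) sides.
* **Transverse** — 2-D Stokes flow across the lattice, driven by a body
  force equal to the mean pressure gradient, on the periodic half cell with
  free-slip symmetry lines, discretized on a MAC staggered grid. In the
  fully periodic creeping regime this is equivalent to imposing a pressure
  drop across a strip of cells, with no entrance effects by construction.

Cylinder walls are handled sharply: stencil arms crossing a wall are
shortened to the exact crossing (Shortley-Weller), which keeps the
nanometre-scale inter-fibre gaps accurate at moderate resolution. The
default resolution policy targets >= 10 cells across the narrowest gap
(capped at 352 cells/pitch). Verification: plane-Poiseuille channel
recovered to 0.1%; a manufactured periodic Stokes solution converges at
second order; the dilute limit matches the original Kuwabara cell model to
0.2% (VF_ECS = 0.95) and the dense limit tracks hexagonal lubrication
theory; axial values agree with the Drummond-Tahir hexagonal closed form to
four digits at high porosity.

Permeability follows from Darcy's law `k = v_mean mu L / dp` with `v_mean`
the superficial average (whole-cell, fibres included). The defaults dp = 5 Pa
(low enough for creeping flow) and L = 0.15 um (axial) are protocol values;
k is independent of dp, L and mu, and the tests assert this.

**Law fitting.** Simulated (vf_ecs, k) points are fitted with two
closed-form families in the solid fraction phi = 1 - VF_ECS:

    k_par  = r^2 / (A phi) * (B + C(-ln phi) + D phi + E phi^2 + F phi^4)
    k_perp = r^2 / (A phi) * (B + C(-ln phi) + D phi + E phi^2)

(the Tamayol-Bahrami and Kuwabara forms). Fitting minimizes log-permeability
residuals, since k spans three orders of magnitude across the sweep. Any
coefficient subset can be fitted with the rest fixed; the leading
denominator coefficient shares an overall scale with the bracket, so at
least one coefficient must stay fixed (an all-free fit is rank-deficient and
raises). The tabulated default coefficients — (2.97, -1.47, -0.94, 2, -0.5,
-0.039) parallel, (7.77, -1.56, -1.04, 2.05, -0.5) perpendicular — carry two
decimals, and at low VF_ECS both brackets are small differences of O(1)
terms: the perpendicular bracket even turns negative below VF_ECS ~ 0.29.
Where the fixed bracket is smaller than its propagated rounding uncertainty
(0.005 x the basis-term sum per coefficient; `coeff_precision` parameter),
the model value is rounding noise, so those sweep points are excluded from
fixed-bracket fits and reported in the fit diagnostics.

## Infusion solver

A structured finite-volume scheme on the imaging voxel grid (the inputs are
voxel images; grid-refinement testing replaces body-fitted mesh
sensitivity). Tensor fluxes use two-point differences with harmonic face
averaging for the face-normal component plus central differences on
face-averaged tensors for the cross terms; the cross-term treatment is
first-order accurate near strong tensor jumps.

* **Pressure**: `div(-(K/mu) grad p) = q` with the catheter as a volumetric
  source (rate Q distributed over the voxels whose centres fall within one
  tip radius, falling back to the containing voxel; the orientation vector
  is recorded for the metrics) and p = 0 on the outer surface. The 1 mm
  catheter is sub-voxel at imaging resolution: the volumetric source
  reproduces the inlet's injected flux integrally rather than its velocity
  profile pointwise. Direct sparse factorization up to ~80k unknowns,
  ILU-preconditioned LGMRES beyond. The discrete scheme is conservative:
  summed boundary outflow equals Q to the solver tolerance (tested at
  1e-6 relative).
* **Transport**: operator splitting per step — explicit first-order upwind
  advection on the face fluxes (sub-stepped to CFL <= 0.5, logged),
  backward-Euler diffusion with a cached factorization, exact exponential
  decay `exp(-lambda dt)`. The solute source injects Q c0 per unit time
  at the tip voxels (flux form; for outward flow this coincides with
  holding the inlet at c0). The outer boundary is zero-solute-flux even
  where fluid drains — the glia limitans blocks drug migration — so the
  mass budget closes as d/dt(int c) = Q c0 - lambda int c, verified per
  step to 0.1%. Upwinding keeps 0 <= c <= c0; the tiny over/undershoots
  that tensor cross terms can introduce are removed by a conservative clip
  recorded in the budget (zero on axis-aligned phantoms).
* **Loss term**: the printed unit of the loss rate (1/min) identifies it as
  a first-order rate constant; it is applied as exact exponential decay.
* **Viscosity**: mu = 1e-3 Pa s by default (water-like interstitial fluid),
  configurable.

Defaults mirror the infusion protocol: Q = 3 uL/min (= 5e-11 m^3/s),
c0 = 0.5 mol/L (= 500 mol/m^3), 180 s total, loss 0.01/min, catheter
diameter 1 mm, outer time step 2 s.

## Metrics

The infusion region is the set of voxels with c > 2.5% of c0. Comparisons
between two simulations report:

* **RMSD** `(1/c0) sqrt( sum_i V_i (cA_i - cB_i)^2 / V(A u B) )` over the
  union of the two regions (the per-element volume V_i cancels on a uniform
  grid but is kept explicit for future nonuniform grids);
* **theta**, the angle between the regions' first PCA axes — PCA of the
  unweighted voxel-centre coordinates (a concentration-weighted variant is
  available behind a flag), compared with the absolute dot product since
  PCA signs are arbitrary;
* **L_max**, the extent of the region projected on its PCA axis plus one
  voxel edge so a single voxel has nonzero support (a tip-anchored variant
  would be an alternative reading; the projection extent is the default);
* **overlap**, Jaccard |A n B|/|A u B| in percent by default, with
  intersection-over-smaller available since published overlap figures do
  not always state the denominator;
* **t statistics** across the nine-orientation protocol (one-sample
  one-sided against zero, or paired two-sided), with n-1 degrees of
  freedom; normality is assumed, not re-tested.

The nine-orientation protocol runs paired DTI / DTI-NODDI simulations with
the catheter along +-x, +-y, z and the four solid-angle bisectors
(+-1, +-1, 1)/sqrt(3).

## Phantoms

Synthetic datasets with exact ground truth replace subject data in all
tests: uniform WM slabs (single fibre direction, constant FA and VF_ECS),
curved bundles (fibre directions tangent to a circular arc), and stacked
CSF/GM/WM slabs. Defaults: 2 mm isotropic voxels (matching the consumed
imaging protocol; solver studies also use 1 mm), FA 0.7, VF_ECS 0.30 with a
0.05 free-water fraction, grids of 16^3-32^3 so a full 180 s infusion runs
in seconds to tens of seconds on one CPU. The FA <-> eigenvalue map is
closed-form: for eigenvalue ratio t = l_perp/l_par,
FA = (1 - t)/sqrt(1 + 2 t^2), inverted as
t = (1 - FA sqrt(3 - 2 FA^2))/(1 - 2 FA^2). Optional multiplicative noise
perturbs FA and VF_ECS while clamping voxels to their intended tissue class,
so segmentation ground truth stays exact.

What the phantoms do **not** emulate: whole-brain anatomy, fibre crossing
and dispersion, imaging noise correlations, partial-volume mixing at tissue
interfaces, or raw DWI signal formation. Passing tests therefore demonstrate
correctness of the numerics and the model algebra on idealized geometry, not
predictive accuracy on subject data.

## Numerical choices and limitations

* Problem sizes: the microscale sweep uses 12 VF_ECS values at the default
  resolution policy (~10 s total); solver oracle tests run on 12^3-33^3
  grids; the direction-following study uses a 32^3 grid at 1 mm.
* The threshold-volume functional is quantized in whole voxels (~3% per
  voxel at 1 mm on the standard phantom). Combined with first-order upwind
  smearing of the plume front, the infusion volume still changes by ~7%
  between 1 mm and 0.5 mm grids; the convergence test asserts monotone
  error contraction across a three-grid sequence rather than a fixed band,
  which would require ~0.25 mm grids to reach.
* The permeability laws were fitted for WM only; GM keeps a scalar
  permeability. Constant-radius straight cylinders are a strong idealization
  of axonal geometry (no dispersion, beading, or polydispersity).
* VF_ECS outside [0.15, 0.80] is clamped to the fitted range and counted in
  the run log.
* Degenerate inputs: zero tensors get FA = 0 (background/CSF convention);
  infusion regions smaller than 2 voxels have no PCA direction and raise;
  zero-variance orientation samples make the t statistic undefined and
  raise.
* Catheter backflow along the shaft, poroelastic deformation, multi-catheter
  interference and tumour tissue are out of scope.
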