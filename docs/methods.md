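# Methods

`gliomech` simulates the growth of a localized brain tumour as a mechanical
process: the tissue is a saturated two-phase mixture of hyperelastic cells
and interstitial fluid, proliferation inflates the solid phase, and the
resulting finite deformation displaces the surrounding tissue, drives Darcy
flow, and reorients the white-matter fibre directions that steer diffusion
and permeability.  All quantities use mm / day / MPa.

## Continuum model

**Phases and regions.**  At every point the solid (cell) fraction phi_s and
fluid fraction phi_l satisfy phi_s + phi_l = 1.  A smooth indicator
chi in [0, 1], fixed on the reference configuration, marks the tumour; the
conventional tumour region is the upper level set {chi > 0.1}.  The
indicator is never advected: the problem is solved in the Lagrangian frame,
so material points keep their label.

**Kinematics.**  The solid deformation gradient is split multiplicatively,
F_s = F_e F_g with F_g = g I: growth is an isotropic, stress-free inelastic
distortion with stretch g >= 1, and F_e is the elastic accommodation.
J_s = J_e J_g with J_g = g^3.  Mass conservation ties the solid fraction to
the deformation: J_s phi_s = J_g phi_sn, where phi_sn = 0.3 is the solid
fraction of the stress-free natural state.

**Elasticity.**  Brain tissue is mechanically near-isotropic, so the elastic
energy per unit natural volume is an isochoric two-parameter Mooney-Rivlin
term plus a logarithmic volumetric term,

    W = mu1/2 (I_Cbar - 3) + mu2/2 (II_Cbar - 3) + kappa/2 (ln J_e)^2,

with Cbar_e = J_e^(-2/3) C_e.  Viscoelastic rate effects are neglected
(growth strain rates are tiny).  Tumour and host carry separate parameter
sets; the solid Cauchy stress is blended pointwise,
T_s = chi T_s^t + (1 - chi) T_s^h, evaluated at the element quadrature
point of the interpolated indicator.  (For this energy the stress is linear
in (mu1, mu2, kappa), so stress blending and parameter blending coincide.)
The defaults make the tumour ten times stiffer than host tissue
(mu1 = 1.53e-3 / 1.53e-4 MPa, mu2 = 2.97e-3 / 2.97e-4 MPa,
kappa = 1.4e-3 / 1.4e-4 MPa).

**Fluid and nutrients.**  The mixture momentum balance reads
Div(-J_s p F_s^-T + P_s) = 0 with p the incompressibility pressure, and the
fluid mass balance reduces to a Darcy problem for p with mobility
k(J_e) A / mu; the dynamic viscosity mu cancels identically (the
permeability tensor is defined as mu k A), so the code stores the mobility
k A directly.  k(J_e) is the Holmes-Mow law

    k = k0 ((J_e - phi_sn)/(1 - phi_sn))^alpha0 exp(m (J_e^2 - 1)/2),

k0 = 2.17e5 mm^2/(MPa day), alpha0 = 0.0848, m = 4.638: the mobility falls
to zero as compression closes the pores (J_e -> phi_sn) and stiffens under
dilation.  Nutrients (normalized oxygen, c_n in [0, 1]) are advected by the
fluid, diffuse along the tensor D, and react only in the tumour:
G_n = -zeta phi_s phi_l c_n + S_n (1 - c_n) phi_l, with consumption
zeta = D_n / l_n^2 = 8640 /day (oxygen diffusivity 86.4 mm^2/day over a
0.1 mm uptake length) and supply S_n = 1e4 /day.  The zero of G_n at
c* = S_n / (S_n + zeta phi_s) is the interior equilibrium concentration
(~0.794 at phi_s = 0.3) that the tumour core approaches away from the
c = 1 boundary.

**Growth law.**  The volumetric proliferation rate is
Gamma_s = gamma phi_s (phi_max - phi_s)(c_n - c0)_+, gamma = 0.5 /day,
hypoxia threshold c0 = 0.3, contact-inhibition cap phi_max = 0.85.
Optionally compression inhibits growth through the factor
1 - delta1 Sigma_+/(Sigma_+ + delta2) with Sigma = -tr(T_s)/3; traction
never inhibits.  delta1 in 0.8-0.9 bounds the maximum reduction and
delta2 in 1e-3-1e-4 MPa sets the compression scale.  g evolves by
g_dot/g = Gamma_s/(3 phi_s) inside the reference tumour region only.

**Tensor fields.**  The initial diffusion tensor D0 is a per-cell symmetric
positive-definite field (from a voxel grid by barycentre ownership,
half-open voxel intervals).  The preferential-direction tensor A0 shares
D0's eigenvectors with eigenvalues reweighted by a1(r), a2(r) built from
the linear/planar/spherical anisotropy indices and normalized to tr A0 = 3.
Under deformation only the fibre *directions* change: eigenvectors are
pushed by F_s and renormalized, eigenvalues kept, so tr D is preserved (A
is rescaled back to trace 3).  The weights a1, a2 are those built from the
*initial* eigenvalues.  The governing equations use the Lagrangian
pullbacks D* = J F^-1 D F^-T and K* built from A.  The default r = 1 means
no anisotropy enhancement; the choice is exposed in the configuration.

## Discretization

Equal-order P1 tetrahedral elements for u (clamped on the outer boundary —
the skull), p and c_n (Dirichlet p = 0, c = 1 by default; zero-flux
variants are available, with one pressure node pinned to fix the Neumann
gauge).  Time stepping is semi-implicit Euler with dt = 0.1 day: each step
solves the monolithic nonlinear system for (u, p, c) with g, phi_s, chi and
Sigma frozen at the previous level, then updates g by explicit Euler (using
previous-level Gamma_s) and phi_s from mass conservation.  Initial
conditions: u = 0, p = 0, c = 1, g = 1, phi_s = phi_sn.

Numerical choices worth knowing:

* **Quadrature.**  One-point (barycentre) quadrature for all terms with
  cellwise-constant integrands (exact for P1), the exact P1 mass matrix for
  the time-derivative terms, and *nodal (lumped) quadrature for the
  nutrient reaction*: the reaction rate (zeta phi_s + S_n ~ 1.3e4/day) is
  far too stiff for the mesh to resolve the boundary layer
  (width sqrt(D/rate) ~ 0.1 mm), and a consistent reaction matrix then
  rings across elements; lumping keeps the nodal interior equilibrium exact
  and monotone.
* **Linearization.**  The Newton residual is always exact (including the
  u-dependence of the reoriented, pulled-back tensors K*, D*).  The Newton
  matrix keeps all stiff couplings — the tangent dP/dF is obtained by
  per-cell central finite differences of the total first Piola stress
  (step 1e-7), avoiding a hand-coded fourth-order elasticity tensor — and
  drops the weak ones (dK*/du, dD*/du, and the u-derivatives of the
  nutrient equation).  Dropped Jacobian blocks affect only the iteration
  path, never the converged solution.
* **Factorization reuse.**  The sparse LU (SuperLU, COLAMD) of the Newton
  matrix is cached across iterations and steps and rebuilt whenever the
  residual contracts by less than a factor 2.  Convergence demands each
  residual block (momentum, Darcy, nutrients) to drop below
  rtol = 1e-8 relative to its step-start value plus atol = 1e-10, with at
  most 25 iterations; a non-converging step raises with the residual
  history.
* **CFL monitoring.**  After each step the advective cell Courant number
  max |v_l| dt / h_cell is recorded (v_l from Darcy's law with
  v_s = (u_{k+1} - u_k)/dt); the default phantom runs stay far below 1.
* **Degenerate inputs.**  Inverted elements (J_s <= 0), pore closure
  (J_e <= phi_sn) and saturation violations (phi_s outside (0, 1)) raise
  immediately rather than being clamped.

## Synthetic phantom

No clinical images ship with the package; the `phantom` module generates
the study inputs.  The "brain" is a ball of radius 40 mm (large enough that
the c = 1 boundary is far from the tumour), meshed by Delaunay
triangulation of a body-centred-cubic interior lattice (background size
h = 8 mm, refined ~2.5x in a ball around the tumour) plus a Fibonacci
covering of the sphere; a small deterministic jitter removes the degenerate
cospherical point sets a perfect lattice would feed the triangulator.  The
tumour indicator is chi = (1 - tanh((|X - c| - r0)/w))/2 with r0 = 7 mm and
w = 1 mm, so the chi > 0.1 region is a ball of radius r0 + w atanh(0.8).
Synthetic DTI voxel grids (2 mm spacing) come in three flavours: isotropic
(FA = 0), uniform-axis, and radial fibre patterns, with prescribed
eigenvalues (default isotropic at the oxygen diffusivity 86.4 mm^2/day).

What the phantom does *not* emulate: cortical folding and ventricles,
grey/white segmentation, spatially varying DTI noise, susceptibility
artefacts, and tumour-induced fibre destruction.  Tests passing on the
phantom therefore validate the solver and the model mechanics, not
patient-level predictions.

## Study conditions and problem sizes

The qualitative acceptance runs use the coarse isotropic phantom
(~1.5k nodes / 7.3k cells), dt = 0.1 day and a 10-day horizon — sizes
chosen as a desk-scale version of the published 45-day patient-geometry
simulations, which are not reproducible without the clinical images.  On
these conditions the simulations reproduce the reported structure:
compression Sigma > 0 in the tumour core with a tensile (Sigma < 0) annulus
outside the interface, negative fluid pressure inside the tumour (fluid is
consumed by growth), displacement peaking at the interface and decaying
outward, slower growth under stress inhibition, and faster growth for
stiffer tumours.

## Known limitations

* No contact with the skull: the boundary is clamped, appropriate while the
  tumour is far from it.
* Quasi-static, isotropic growth; no anisotropic growth tensor.
* No vascular collapse or perfusion loss; nutrient supply is spatially
  uniform inside the tumour.
* Equal-order P1-P1 displacement-pressure pairing can oscillate for
  incompressible limits; at the soft, compressible parameter set used here
  it is well behaved (the zero-source fixed-point and free-growth patch
  tests are exact to solver tolerance).  An element-size-scaled
  pressure-gradient stabilization of the Darcy block is available
  (`pressure_stabilization` in the configuration) and off by default.
* Eigenvector-change maps are only meaningful where the initial tensor is
  anisotropic; cells with FA <= 0.1 are masked.
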