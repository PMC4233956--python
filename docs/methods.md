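# Methods

## Model

`ibfelv` simulates the passive inflation of the left ventricle (LV) during
diastole with a hybrid immersed-boundary/finite-element (IB/FE) method.  The
coupled fluid–structure system is described on two grids at once:

* an **Eulerian** description of momentum, viscosity and incompressibility on
  a fixed staggered (MAC) Cartesian grid covering a cubic box Ω (15 cm per
  side by default): velocity components on cell faces, pressure at cell
  centers;
* a **Lagrangian** description of the myocardial wall on an unstructured
  8-node hexahedral mesh carrying the elastic stress.

The two descriptions are linked by integral transforms with a regularized
Dirac kernel: the structure moves with the locally interpolated fluid
velocity (no-slip), and the elastic force density of the structure is spread
to the fluid grid, where it enters the momentum equation.  Fluid and solid
share the density ρ = 1 g/cm³ and viscosity μ.  Incompressibility of the
whole composite is imposed through the Eulerian pressure.

### Passive myocardium

The wall is a hyperelastic orthotropic Holzapfel–Ogden material defined by
the invariants I₁ = tr C, I₄f = f₀·Cf₀, I₄s = s₀·Cs₀, I₈fs = f₀·Cs₀ of
C = FᵀF and the local fiber/sheet axes f₀, s₀:

    W = a/(2b) exp[b(I₁−3)]
      + Σ_{i=f,s} a_i/(2b_i) {exp[b_i (max(I₄i,1)−1)²] − 1}
      + a_fs/(2b_fs) {exp[b_fs I₈fs²] − 1}.

The `max(I₄,1)` switch makes the fiber and sheet families tension-only.
Default constants (a = 0.2362 kPa, b = 10.81, a_f = 20.037 kPa,
b_f = 14.154, a_s = 3.7245 kPa, b_s = 5.1645, a_fs = 0.4108 kPa,
b_fs = 11.3) are the standard porcine simple-shear fit for healthy
myocardium.  All internal computation is CGS (1 kPa = 10⁴ dyn/cm²,
1 mmHg = 1333.22 dyn/cm²).

### Modified stress variants

Four first Piola–Kirchhoff stress variants are available:

* `raw` — P = ∂W/∂F.  At F = I this leaves a residual isotropic stress a·I,
  which the Eulerian pressure must balance through a discontinuity at the
  fluid–solid interface; discretely this causes spurious volume loss.
* `pressure_normalized` — P − aJF⁻ᵀ.  The subtracted term is the
  push-forward of a constant Cauchy pressure a, so the stress vanishes
  identically in the reference configuration and the leading interface
  pressure jump is moved from the Eulerian grid into the Lagrangian stress.
  Its generating energy is W − a(J−1).
* `penalized` (default) — additionally β_s log(J) F⁻ᵀ from the volumetric
  penalty U_vol = (β_s/2)(log J)², β_s = 5·10⁶ dyn/cm², which imposes
  incompressibility approximately in Lagrangian form.  (The penalty form is
  a design choice of this package: it vanishes with zero stress at J = 1
  and is monotone around it; it is exposed per-variant rather than
  hard-wired.)
* `penalized_no_ps` — penalty without pressure normalization (for the
  modification study).

In the continuum the variants differ only by pressure-like fields and give
identical dynamics; discretely they change the accuracy of recovered stress
and the Lagrangian volume conservation, which is exactly what the
verification experiment measures.

### Spatial discretization

*Eulerian*: standard second-order staggered-grid operators.  Boundary
conditions on all six walls are zero tangential slip and zero normal
traction; for incompressible flow along a flat no-slip wall the latter
reduces to p = 0 on the wall and a homogeneous Neumann condition on the
wall-normal velocity.  These reflection symmetries make every operator
diagonal in mixed DCT-I/DST-II bases, so the Crank–Nicolson viscous
Helmholtz solves and the pressure projection are performed by fast
transforms and the saddle system is solved *exactly* (momentum and
continuity residuals at round-off).  This replaces the block-multigrid
Krylov solver used by large-scale IB implementations; the solver contract,
not the algorithm, is what matters at this scale.  The convective term uses
a second-order upwind-biased (one-sided three-point) reconstruction — the
target flows are quasi-static, so a full PPM reconstruction is not needed;
next to tangential walls the stencil falls back to first order rather than
crossing the wall.

*Lagrangian*: trilinear hexahedra with 2×2×2 Gauss quadrature.  The nodal
elastic force density F is defined weakly through the consistent mass
matrix, M F = −∫P:∇φ dX + surface terms, and recovered by a sparse direct
solve (tolerance is that of the LU factorization; force-projection accuracy
bounds stress accuracy).  Selective reduced integration prevents volumetric
locking: the pressure-normalization and penalty terms are evaluated from
the deformation at the single-point rule.  One refinement: the constant
isotropic part −a·I of the pressure normalization is carried in the
full-rule integral (the two placements differ only by a
deformation-independent quadrature defect on curved elements, but this
placement makes the reference-state force density *exactly* zero on any
element geometry, which the coupled scheme needs to preserve equilibrium),
while the deformation-dependent parts stay at the reduced point.

*Coupling*: the tensor-product four-point Peskin kernel on each staggered
component's face lattice.  Interaction quadrature is regenerated every step
(configurations change slowly; the order-dependent structure is cached) as
per-element Gauss rules with at least two points per Cartesian mesh width
along every deformed edge.  Spreading and interpolation use the same points
and weights, making them exact adjoints; the structure velocity is the L²
projection of the interpolated field onto the FE space through the
consistent mass matrix.  Simulations must keep the structure ≥ 2h from ∂Ω
(checked every step) so the kernel never leaves the domain.

### Time stepping

Explicit midpoint rule for the structure combined with Crank–Nicolson
viscosity and Adams–Bashforth (AB2) convection for the fluid: positions are
advanced to the half step with the kernel-restricted velocity, the elastic
force at the half step is spread, one Stokes solve produces u^{n+1} and the
half-step pressure, and positions are completed with the midpoint velocity.
The first step replaces the unavailable lagged convective term by an
explicit midpoint predictor (one additional Stokes solve).

The default Δt comes from a stability heuristic
Δt ≤ safety · h_min/√(E_max/ρ) with h_min the smallest structural edge and
E_max a tangent-stiffness scale (penalty β_s plus the instantaneous
isotropic and fiber moduli at the current strain), safety 0.5.  If a run
blows up the error message recommends bisecting Δt downward, mirroring how
the reference Δt of such models is chosen in practice.

### Boundary and loading conditions

A spatially uniform endocardial pressure is applied as a follower load
(traction −p n da over the deformed endocardial faces), ramped linearly to
7.5 mmHg and held until the model reaches steady state.  Circumferential
and longitudinal displacements of the basal plane are suppressed by nodal
penalty forces in cylindrical components (stiffness κ_bc, default
10⁷ dyn/cm⁴ — not a physical constant; chosen so that basal in-plane motion
stays far below 1% of the wall displacement without affecting the stable
Δt); radial motion of the base and the entire remaining wall surface,
including the apex, are free.  The static reference solver imposes the same
basal constraints *exactly* by eliminating the constrained cylindrical
degrees of freedom.

### Synthetic left ventricle

Because the subject-specific image-derived mesh of the original study is
not deposited, the geometry module generates a truncated prolate
ellipsoidal shell (defaults: endocardial semi-axes 2.5/5.5 cm, epicardial
3.6/6.5 cm, basal plane at z = 2 cm; long axis +z, base up).  The shell is
meshed with structured hexahedra in (transmural, circumferential,
longitudinal) parameters and the apical pole is closed by a structured
square-patch cap whose boundary ring coincides with the last shell ring
(this requires the circumferential count to be a multiple of 8); all
elements are checked for positive Jacobians.  The rule-based fiber
architecture rotates the helix angle linearly in the transmural coordinate
e from −60° (endocardium) to +60° (epicardium) and the sheet angle from
−45° to +45°; linear-in-e interpolation is the simplest monotone choice
consistent with the usual rule-based construction (the alternative,
linear-in-arc-length, differs only at second order for this wall).  The
local basis uses the gradient of e as the radial direction and the azimuth
about the long axis for the circumferential direction, with a documented
fallback on the axis.

What the synthetic LV does *not* reproduce: regional wall-thickness
variation, trabeculation, the right ventricle and atria, and the
image-based fiber dispersion of a real ventricle.  Verification results on
it therefore validate the *numerical scheme* (dynamic IB/FE vs static FE on
identical inputs), not patient-specific stress magnitudes.

### Static reference solver

The benchmark role of a commercial FE solver is filled in-repository by a
quasi-static Newton solver on the same mesh/material/loading with exact
basal constraints and follower pressure.  The tangent is assembled by
batched central finite differences of the element (and pressure-face) force
vectors — exact to O(ε²) and automatically consistent with the residual —
with load continuation (adaptive increment halving/doubling, a secant
predictor between increments, a trust region of half the smallest element
edge, and strictly monotone backtracking on ‖R‖₂).  Forward differences are
deliberately avoided: their O(β_s·ε) truncation exceeds the stiffness of
the softest hourglass modes near the reference state and renders the
tangent indefinite.  Incompressibility uses the same volumetric penalty as
the IB model so that the comparison isolates the coupling scheme.

## Scaled verification protocol

The verification experiment inflates the synthetic LV twice — dynamically
(IB/FE, run to steady state) and statically — and compares displacement
fields plus logarithmic fiber strain ln λ_f = ½ ln I₄f and fiber Cauchy
stress σ_ff along seven transmural paths across the free wall (relative
difference per path = mean |Δ| / mean |static reference|, a definition this
package fixes since the quantity is conventionally plotted without one).

Problem sizes are chosen for a single desk CPU: LV meshes of 288 elements
(2×16×8 plus cap) for the coupled runs and Eulerian grids N = 32 and 48;
the acceptance script and test suite state their sizes in their output.
Two protocol parameters deviate from the full-scale study and are pure
*transient* devices (the steady state they lead to is provably independent
of both):

* fluid viscosity μ = 60 g/(cm·s) instead of 0.04.  With the physical
  value the slow chamber-breathing mode rings for seconds of physical time;
  60 is near critical damping of that mode for this geometry, so the model
  creeps monotonically to equilibrium within ~0.2 s of physical time.  At
  equilibrium the fluid is at rest and viscosity drops out of the force
  balance entirely.
* pressure ramp of 0.12 s followed by a hold, with termination when the
  maximum nodal structure speed falls below 0.02–0.05 cm/s (the full-scale
  study's own endpoint has residual velocities of ~0.3 cm/s).  The
  kinetic-energy history is logged and the final/peak ratio is reported so
  a run that has not actually reached the quasi-static limit is visible.

No artificial structural damping is used anywhere.

The incompressibility study reruns the inflation with the volumetric
penalty off (`raw`) and compares min/max J at the reduced quadrature
points; the stress-modification study compares the IB-vs-static strain and
stress discrepancies of the unmodified and fully modified variants.

## Numerical choices and degenerate inputs

* Exponential overflow: arguments above 50 are clamped with a warning
  rather than returning inf.
* Inverted elements (det F ≤ 0) raise immediately, naming the elements.
* Newton line search treats element inversion in a trial step as a failed
  step (halve), not an error.
* Quadrature orders for the interaction rules are capped at 8 per
  direction.
* Non-finite structure states are detected before they reach the
  scatter kernels.
* Ties/degeneracies: basal nodes on the long axis (undefined azimuth) are
  an error; the apex-axis fiber fallback uses a fixed in-plane direction.

## Known limitations

* Trilinear hexahedra under near-incompressible bending are stiff; at the
  desk-scale resolutions the static spherical-shell oracle converges as
  ~7.8% → 2.1% → 0.9% under refinement, and the LV comparison inherits a
  few-percent discretization floor at N = 32–48 that the full-scale study
  resolves only at N ≳ 96.
* The explicit coupling is only marginally stable for the stiffest penalty
  modes when the fluid damping is weak (μ ≲ 10 at these grids); the
  protocol's μ = 60 removes the issue, and full-scale runs at the physical
  μ require the (much smaller) bisected Δt of the original study.
* Flow fields during the transient are not physiological (no valves, open
  basal plane); only the quasi-static end state is meaningful.
* Active tension, viscoelasticity and residual stress are out of scope.
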