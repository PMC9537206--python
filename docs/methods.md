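# Methods

`stenoflow` simulates pulsatile, incompressible, shear-thinning blood flow
through an idealized axisymmetric stenosed vessel and post-processes the
wall shear stress (WSS) into the index chain TAWSS → OSI → RRT, across a
sweep of stenosis severities. This note records the model, the numerical
choices, and what the synthetic study conditions do and do not represent.

## Physical model

**Governing equations.** Unsteady incompressible Navier–Stokes in
axisymmetric (r–z) form with variable apparent viscosity:

    ∇·v = 0
    ρ(∂v/∂t + v·∇v) = −∇p + ∇·τ,     τ = μ(γ̇)(∇v + ∇vᵀ)

Body and external forces are dropped: in rigid-wall incompressible flow a
gravitational field only shifts the pressure hydrostatically and leaves
the velocity field and all wall-shear indices unchanged. The flow is
treated as laminar throughout; the default study conditions keep the
Reynolds number at a few hundred.

**Rheology.** The Carreau-Yasuda law

    μ(γ̇) = μ∞ + (μ₀ − μ∞) / (1 + (λγ̇)^a)^((1−n)/a)

with the standard whole-blood constants μ₀ = 0.056 Pa·s, μ∞ = 0.0035 Pa·s,
λ = 3.313 s, n = 0.3568, and density ρ = 1060 kg/m³. The Yasuda exponent
defaults to a = 2, which reduces the law to the classic Carreau blood
model consistent with those four constants; it is exposed in the
configuration for sensitivity studies. The shear-rate argument is the
frame-invariant magnitude γ̇ = √(2 D:D) of the rate-of-deformation tensor
D = (∇v + ∇vᵀ)/2 — in the axisymmetric frame this includes the hoop
component v_r/r. (Simpler "printed" forms of the WSS radicand that omit
the contraction are dimensionally inconsistent; the invariant definition
is the one the rheology literature uses.)

**Geometry.** A straight circular tube of inlet radius R₀ with a C¹
cosine area-reduction bump of compact support:

    r_wall(z) = R₀ √(1 − S·b(z)),  b(z) = ½(1 + cos 2π(z−z_c)/L_s) on |z−z_c| ≤ L_s/2.

Severity S is defined as the **area**-reduction fraction at the throat
(not the diameter reduction): the throat cross-section is exactly
(1 − S)·πR₀². Under this convention the continuity-based throat
velocity amplification is 1/(1 − S), which crosses the factor of two at
S = 0.5 — consistent with the qualitative observation that blockages past
50 % roughly double the peak of the velocity waveform while milder ones
do not. The cosine bump (rather than, say, a Gaussian) keeps the healthy
sections exactly cylindrical, so "healthy" comparisons are clean.

**Scale of the default conditions.** The defaults use a small-vessel
geometry — R₀ = 1.5 mm, length 30 mm, stenosis length 4 mm (inside the
2–6 mm range typical of the focal lesions idealized here), peak mean
inlet velocity 0.5 m/s at 70 bpm. At blood viscosities this yields
Re ≈ 200–700 and a Womersley number α ≈ 2, firmly laminar and resolvable
on a desk-scale grid. These conditions are an idealized analogue of an
arterial blockage, not a patient-specific aorta: absolute magnitudes
(pressures in a 3-D arch with branches, patient pressure tables) are out
of reach of this geometry by design; the cross-severity *trends* of the
indices are the object of study.

## Boundary conditions

The clinical boundary waveforms exist only as recorded figures, so they
are emulated parametrically (all shape constants configurable):

* **Inlet velocity** (cross-section mean): a sin² systolic ejection pulse
  of height `peak_velocity` over the first `systolic_time_fraction`
  (default 0.35) of the cycle, followed by a brief sin² reverse-flow
  notch of depth `reverse_fraction` × peak (default 0.15) over 0.10 of
  the cycle, zero for the rest of diastole. The radial profile is
  parabolic, scaled so the area mean follows the waveform (no profile
  information is available to do better; any smooth profile washes out
  within a few radii).
* **Outlet pressure**: a raised-cosine pulse through the smooth monotone
  time warp g(x) = x + (β/2π)(1 − cos 2πx), β = 0.4, which skews the
  systolic peak early while keeping the waveform C¹ across the periodic
  seam; maximum and minimum are exactly the systolic/diastolic settings
  (defaults 120/80 mmHg, 1 mmHg = 133.322 Pa).
* Rigid no-slip wall and symmetry axis.

The vessel has a single outlet; multi-branch arrangements are a geometry
feature outside this package's scope.

## Discretization and solution algorithm

Finite-volume on a body-fitted structured grid: axial stations carry
radial lines scaled to the local wall radius (η = r/r_wall(z) ∈ [0,1]),
with optional geometric near-wall clustering (default growth rate 1.2).
All cell volumes and face areas are those of the revolved quadrilaterals
(Pappus), so the annular areas at a station partition the disc to
round-off and discrete conservation statements are exact.

* **Time**: BDF2 (second-order implicit) with one backward-Euler startup
  step. The step defaults to 0.01 s and is snapped to an integer number
  of steps per cardiac cycle.
* **Convection**: first-order upwind, implicit, using the divergence-free
  face fluxes of the previous inner iterate. Upwinding adds numerical
  diffusion in the post-stenotic shear layer; it buys unconditional
  stability at the physiological CFL numbers the 0.01 s step implies.
  The validation oracles (Poiseuille, Womersley) are convection-free, so
  their accuracy checks are not masked by it.
* **Diffusion**: μ-lagged Laplacian form with face-interpolated apparent
  viscosity plus the axisymmetric hoop sink −μ v_r/r². The ∇μ·(∇v)ᵀ
  transpose terms are neglected: they vanish identically for constant
  viscosity and for unidirectional shear (the near-wall regime that sets
  the WSS), and their omission keeps the momentum operator a clean
  five-point stencil.
* **Pressure–velocity coupling**: incremental pressure projection on the
  collocated grid. Predictor face fluxes are interpolated from the
  momentum solution; the pressure-increment Poisson equation is
  assembled from compact face-normal gradients (orthogonal
  approximation; the grids are mildly non-orthogonal only inside the
  bump) and solved by a cached sparse LU factorization, so the discrete
  continuity residual is at machine precision and inflow equals outflow
  at every instant by telescoping. Cell velocities are corrected with
  the wide mapped-coordinate gradient; this two-velocity arrangement is
  the standard cure for collocated odd–even decoupling.
* **Gauge pressure**: the solver works in pressure relative to the
  instantaneous outlet value. A spatially uniform offset has no dynamic
  effect, and removing it prevents the time-varying outlet Dirichlet
  value from injecting a spurious one-cell gradient spike each step.
* **Picard inner iterations**: the apparent viscosity and the convecting
  fluxes are re-evaluated within each step until the relative L2 change
  of the viscosity field drops below `picard_tol` (default 10⁻³), with
  under-relaxation (default 0.7) to damp limit cycles caused by upwind
  flux switching in the separated shear layer. Exceeding
  `max_inner_iterations` (default 30) raises a non-convergence error
  carrying the residual. Newtonian runs converge in one iteration.
* **Outflow backflow**: momentum inflow through the outlet during
  transient backflow is dropped from the convective operator (standard
  backflow stabilization at an artificial boundary); mass conservation
  is unaffected because continuity is enforced by the projection.
* **Startup**: each pulsatile run initializes from a steady solve at the
  cycle-mean inflow and marches `n_cycles` (default 3) cardiac cycles,
  keeping the final cycle. Three cycles wash the steady-start transient
  below a ~10⁻⁴ cycle-to-cycle periodicity residual at the default
  conditions; the residual is reported, and values above 2 % are
  recorded as warnings rather than errors.

**Wall shear extraction.** At each axial station the signed tangential
traction is τ_w = μ(γ̇_w)·∂u_t/∂n with the wall-normal derivative from a
one-sided quadratic through the two near-wall cell rows and the no-slip
wall value (second-order). Traction is sampled at 100 uniform instants
per cycle (periodic linear resampling of the per-step values) and stored
as tangent-plane vectors; the circumferential component is identically
zero for swirl-free axisymmetric flow, but the index chain is written
for 2- or 3-component vectors.

## Index chain

    TAWSS = (1/T)∫₀ᵀ |τ⃗_w| dt
    OSI   = ½(1 − |∫₀ᵀ τ⃗_w dt| / ∫₀ᵀ |τ⃗_w| dt)
    RRT   = 1/((1 − 2·OSI)·TAWSS)

Quadrature is the composite trapezoid with periodic closure, which on a
uniform grid excluding the period endpoint reduces to the sample mean
times T and is spectrally accurate for smooth periodic integrands; 100
vs 200 samples of the analytic fixtures agree to well under 0.5 %.
Numerical OSI is clamped to [0, 0.5]; positions with identically zero
traction return OSI = 0 by convention so the range invariant stays
testable. RRT is singular at OSI = 0.5: positions with
(1 − 2·OSI) < ε (default ε = 10⁻³) or TAWSS = 0 are flagged and reported
as the capped value 1/(ε·TAWSS) (flagged-infinite when TAWSS = 0), so
tabular outputs stay finite while singular zones remain identifiable.

## Severity pipeline definitions

* **Probe velocity** is the cross-section mean (bulk) axial velocity at
  the probe station, computed from the solved face fluxes; the
  centerline value is recorded alongside. The **amplification factor**
  (peak probe velocity relative to the healthy run) is defined on the
  bulk velocity, for which the quasi-steady continuity estimate
  1/(1 − S) applies; the centerline ratio is systematically smaller
  because the accelerating throat jet flattens the profile.
* **Pressure extrema** at a probe: systolic = cycle maximum,
  end-diastolic = cycle minimum, and mid-diastolic = the value at the
  temporal midpoint of the diastolic interval, which starts a
  configurable `decay_fraction` (default 0.15) of a cycle after the
  systolic peak and ends one period after the peak. "Mid-diastole" has
  no standard formula; this definition is explicit and configurable.
* **Probes** default to the inlet plane, the throat plane, and one
  diameter downstream of the bump — analogues of upstream/lesion/
  downstream measurement points, not replicas of any patient landmark.
* **RRT summary**: order statistics over unflagged positions with the
  flagged count reported separately; an all-flagged profile reports
  absent values. The cross-severity association between systolic inlet
  pressure and maximum RRT is reported as a Spearman rank correlation
  with no significance testing (n = 5 severities).

## What the synthetic conditions do and do not show

Passing tests demonstrate: the rheology law and its limits; exact
discrete mass conservation; second-order spatial convergence on
Poiseuille flow and < 2 % agreement with the analytic Womersley solution;
the OSI bracket identities and RRT singularity handling; and the
continuity-driven cross-severity amplification trend. They do **not**
validate patient-specific magnitudes: the geometry has no curvature,
branches, or compliance, the waveforms are parametric emulations, and
first-order upwinding smooths the post-stenotic recirculation. Reported
TAWSS/OSI/RRT values are therefore comparative across severities, not
clinical predictions.

## Default problem sizes

The default grid is 96 × 24 cells (axial × radial, growth rate 1.2),
86 time steps per cycle, 3 cycles per run; a five-severity sweep
completes in a few minutes on one core. Validation studies use uniform
radial grids of 12–48 cells; the Womersley check runs at α = 4 with 200
steps per cycle. These sizes were chosen so that every reported
quantity sits in its asymptotic convergence range while a full sweep
remains an interactive-scale computation.

## Known limitations

* First-order upwind convection diffuses the separated shear layer;
  recirculation-zone lengths are qualitative.
* The orthogonal approximation in the diffusion and Poisson stencils
  introduces O(slope²) error inside steep bumps (worst ≈ 26° face tilt
  at S = 0.65 with the default 4 mm lesion).
* Very coarse grids (near the 16 × 8 minimum) combined with the full
  shear-thinning law can stall the Picard iteration in the shear layer;
  the default resolution converges in 1–4 inner iterations.
* With a pressure-Dirichlet outlet and a single-branch vessel, the probe
  pressures are pinned to the imposed outlet waveform: cross-severity
  differences in the reported pressure extrema are fractions of a mmHg.
  Reproducing a pressure *rise* with severity would require a
  flow-dependent outlet impedance (Windkessel), which is out of scope;
  the severity signal lives in the velocity amplification and the wall
  indices. The cross-severity rank correlation between systolic inlet
  pressure and maximum RRT is reported for completeness but is dominated
  by these sub-mmHg differences.
* The narrative quantity "OSI > 0.5" sometimes seen in contour
  discussions is impossible under the OSI definition (its range is
  [0, 0.5]); no numeric OSI field values are asserted beyond the bracket
  identities and the range invariant.
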