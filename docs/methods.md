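# Methods

`finprop` studies how a balistiform swimmer — a deep-bodied, laterally
compressed fish that swims by passing traveling waves along its dorsal
and anal fins while holding the body and tail rigid — trades
acceleration against propulsive economy when it folds its caudal fin.
The package couples a parametric swimmer model to a 2-D
immersed-boundary Navier-Stokes solver with a single free streamwise
degree of freedom, and computes the hydrodynamic performance statistics
used to compare caudal-fin opening angles.  A velocimetry module turns
markerless-tracking keypoint tables from tank video into the measured
swimming speeds and fin-beat frequencies that anchor the simulations.

## Swimmer model

The reference swimmer is 57 mm long, 7 mm wide and 40 mm tall, with a
mass of 2.6 g, in artificial seawater at 24 degC (density
1023.6881 kg/m^3, kinematic viscosity 9.5818e-7 m^2/s).  The geometry
module builds a watertight, region-tagged triangle mesh: an ellipsoidal
body, dorsal and anal fin strips modelled as zero-thickness membrane
plates (closed "pillow" triangulations; both faces count as wetted
area), and a caudal fin made of two fan-shaped lobes hinged on the
peduncle axis.  The caudal opening angle phi folds the lobes
symmetrically out of the vertical plane by +-phi/2, which leaves the
model's width unchanged — the presets are 5 deg (closed), 30, 60, and
100 deg (full-open).  Only integral quantities (areas, in-plane chords)
feed the physics, so the body outline is deliberately simple.

## Fin kinematics

Each fin ray at station x rotates about the fin base line by

    theta(x, t) = beta(t) * theta_max * sin(2*pi*(x/lambda + f*t)),

and a point at height z above the base maps to y' = z sin(theta) + y,
z' = z cos(theta) (written via the elongation dz = 2 z cos((pi-theta)/2)
sin(theta/2)), so fin-ray length is exactly preserved.  The startup
coefficient beta limits the first-cycle excursion.  Two modes ship:
`as_printed` evaluates ((t-T)^4 + T^4)/T^4, which equals 2 at t = 0 and
decays to 1 — it *doubles* the startup excursion; `monotone` (default)
is the corresponding true ramp 1 - ((T-t)/T)^4 rising 0 -> 1.  Both are
continuous at t = T.  The anomaly is kept testable rather than silently
resolved.

Peak amplitude theta_max = 30 deg and wavelength lambda = the fin-base
length are defaults chosen because amplitude and wavelength of real
balistiform swimmers stay fixed across speeds while frequency modulates
speed; both are configurable.  Degrees are accepted at every interface
and converted to radians at exactly one internal boundary.

A sign subtlety: the phase x/lambda + f*t propagates crests toward -x.
The 3-D kinematics keeps that form.  The 2-D boundary builder instead
uses x/lambda - t so that the wave runs from head (x=0) toward tail,
the direction the fins actually pass their wave; the swimmer then
propels itself head-first into the body-frame inflow.

## Flow solver

A uniform staggered (MAC) grid carries the 2-D incompressible
Navier-Stokes equations with kinematic pressure.  Time stepping is
three-stage SSP Runge-Kutta with fully explicit advection (divergence
form, 2nd-order central) and diffusion; each stage ends with direct
forcing on the immersed boundary, an outflow flux correction, and a
pressure projection (5-point Laplacian, prefactorised sparse LU by
default, CG with diagonal preconditioning as an option, FFT in periodic
boxes).  SSP-RK3 was chosen over multistep schemes because its
stability region covers the imaginary axis: central advection at the
cell Reynolds numbers of the swimmer runs (~100) produces nearly
neutral modes that destabilise Adams-Bashforth even below its nominal
CFL limit.  At every Reynolds number this package targets (<= a few
thousand) the explicit diffusive limit (0.25 h^2/nu) is slacker than
the advective CFL at the default step, so an implicit diffusion solve
would add cost without enlarging the usable step.  `step()` checks both
limits and raises with the admissible dt; post-projection divergence is
asserted below 1e-8 scaled by max|u|/h every step.

The moving swimmer surface is a set of Lagrangian markers (spacing ~ 1
cell).  Direct forcing interpolates the provisional velocity at the
markers with the Roma 3-point regularised delta, adds the momentum
forcing that drives it to the prescribed marker velocity, and spreads
that forcing back.  Because forcing is applied after each stage's
convex combination, stage forcings propagate into the end-of-step field
with coefficients (1/6, 2/3, 1); the reported surface force is the
correspondingly weighted momentum exchange, sign-reversed.  The
smeared delta widens bodies by roughly 0.4 h per side — the classical
effective-radius bias of diffuse-interface immersed boundaries — so
benchmark geometries retract their markers by 0.4 h; for the
zero-thickness swimmer filaments the bias acts like a slight uniform
thickening and cancels in paired comparisons.  The stage-3 projection
potential equals 2/3 of the physical pressure; the stored field is
rescaled accordingly (verified by radius-independence of momentum-flux
integrals around a towed cylinder).

Validation: Taylor-Green energy decay within 0.1% of exp(-4 nu k^2 t)
at 64^2; 2nd-order spatial convergence over 32/64/128; lid-driven
cavity at Re=100 within 0.5% of the Ghia, Ghia & Shin (1982) centreline
table at 64^2; an impulsively started cylinder at Re=40 gives a drag
coefficient of 1.53 after the standard (1-B)^2 continuity blockage
correction for the free-slip tank walls (B the diameter-to-width
ratio), against the classical steady-wake value of about 1.5.

Boundary conditions for swimmer runs ("tank"): prescribed inflow on the
upstream face (the body-frame far field), a convective outflow
flux-corrected each step so the pressure problem stays compatible, and
free-slip lateral walls.  Wake diagnostics are the out-of-plane
vorticity and the Q-criterion, Q = (||Omega||^2 - ||S||^2)/2, which in
2-D incompressible flow reduces to det(grad u); both are computed at
cell centres by central differences.

## The planar analogue

The full-scale problem is three-dimensional; this package deliberately
reduces it to the horizontal plane in which the dorsal-fin wake
interacts with the caudal fin, at desk scale.  The 2-D swimmer is:

* a rigid elliptical forebody (chord 0.45 L, half-width W/2L ~ 0.061)
  providing friction and form drag;
* an undulating midline filament over x/L in [0.45, 0.80] carrying the
  median-fin wave with edge amplitude A = (H/L) sin(theta_max) ~ 0.105
  and a smoothstep envelope from its attachment point;
* the caudal fin as a V-wedge from the peduncle point (x = 0.84 L) to
  the tail tip, with half-spread w(phi) = (r_lobe/L) sin(phi/2) — the
  lateral offset of the folded lobes.  Closed, the lobes collapse onto
  a single streamlined centreline spike sitting in the fin jet; open,
  they form a bluff V.  The V-wedge represents the frontal bluffness
  the opened 3-D fan presents to the flow — the feature that makes the
  open tail shed a drag (Karman) wake — rather than the literal
  plane-cut of the lobes (two flow-aligned segments), which would
  discard that mechanism.  When the spread is below one grid cell the
  lobes merge so coincident markers do not double-force the same cells.

Analogue runs are nondimensional (length L, time = one undulation
cycle, fluid density 1).  The `reduced` scale targets a swimming-speed
Reynolds number of 500 for the 10 Hz case (scaled by the physical Re
ratio at other frequencies) via nu* = u_ref/Re with u_ref the measured
speed in body lengths per cycle; the `physical` scale uses the real fluid's
viscosity, nu* = nu/(L^2 f).  The default domain is 6 L x 3 L at
256 x 128 cells — cell size L/42.7, chosen so the open-caudal lobe
spread (~0.054 L) spans more than two cells and stays distinguishable
from the closed configuration under the delta-kernel smearing — with
the head at x = 1.5 L.

## Self-propulsion coupling

The swimmer's streamwise speed u_a obeys m du_a/dt = F with F the
integrated surface force, discretised by BDF2,

    u^{n+1} = (4 u^n - u^{n-1} + 2 dt F^{n+1}/m) / 3,

with one backward-Euler step at startup.  F^{n+1} is implicit: each
step extrapolates the speed (2u^n - u^{n-1}), solves the flow with that
inflow, updates the speed, and optionally Picard-iterates (default 2
passes, relative tolerance 1e-6).

Because the flow is solved in the body frame, an accelerating far field
exerts a Froude-Krylov force rho V du_a/dt on the body (V the displaced
area).  For a neutrally buoyant body this term exactly cancels the
inertia, making naive explicit coupling ill-posed — the classical
added-mass instability at density ratio 1.  The update therefore uses
the excess inertia m_eff = m - rho V; the analogue's default density
ratio of 2 makes m_eff equal to the displaced mass (~0.0434 rho L^2 per
unit depth).  This choice sets the acceleration timescale only;
terminal speeds and all closed-vs-open orderings are unaffected.
Default time step: T/200.

## Performance metrics

Over an averaging window (default 20 cycles, truncated with a warning;
the first 0.1 cycle is masked because near-zero speeds make the drag
coefficient and cost of transport singular):

* average acceleration alpha = u_e/t_0, with u_e the measured swimming
  speed and t_0 the simulated time to reach it (alpha t_0 = u_e holds
  identically);
* Reynolds number Re = u_e L/nu;
* thrust/drag decomposition: per-element streamwise forces aligned with
  the swimming direction sum to T_f, the opposing sum's magnitude is D,
  and F = T_f - D holds exactly by construction.  Element-sign
  splitting rectifies marker-level forcing noise, so T_f and D are
  upper bounds on their coherent parts; their difference is unbiased;
* power P_e delivered to the fluid: the fin deformation power plus the
  translation part -u_a F (tank-frame surface velocities);
* Froude efficiency eta = T_f u_a / P_e and cost of transport
  Omega = P_e/(u_a m), both from cycle-averaged inputs over the same
  window;
* drag coefficient: the `standard` convention D/(1/2 rho U^2 s) is the
  physical default; the `as_printed` first-power convention
  D/(1/2 rho U s) is also implemented (it is dimensionally a
  coefficient only together with a unit reference speed), and every
  summary records which convention produced it.

## Velocimetry

Keypoint tables (pose-estimation exports with x/y/likelihood triples,
or plain frame,x,y,confidence CSV) are converted to speed by dropping
samples below a confidence threshold (default 0.9), linearly
interpolating the gaps, smoothing positions with a local least-squares
quadratic (Savitzky-Golay, half-width 5 frames at 60 fps), and central
differencing; the reported u_e is the mean of the top-decile smoothed
speeds — an operational definition of the plateau speed.  Fin-beat
frequency comes from zero crossings of the mean-subtracted lateral
signal (resolution: one crossing quantum, 1/(2 x window)), with a
periodogram peak as an alternative; 29 Hz at 60 fps sits just under
Nyquist and is still recovered.  The frequency-speed relation is an
ordinary least-squares line with Pearson r.

## Synthetic data

The generators provide every input with ground truth attached: tracks
(constant velocity, constant acceleration, ramp-then-plateau; 60 fps;
isotropic Gaussian pixel noise as the pose-estimation jitter proxy;
deterministic under a fixed seed), analytic flow and forcing fixtures
(Taylor-Green, rigid rotation, planar strain, constant and sinusoidal
force, towed cylinder), and complete run configurations for the four
caudal presets at 10 and 29 Hz in either scale.  Synthetic tracks
emulate the sampling and noise of markerless tracking but not its
failure modes (identity swaps, occlusions, confidence miscalibration),
so passing recovery tests bounds estimator error under well-behaved
tracking only.

## What the reduced model does and does not reproduce

At reduced scale the paired closed-vs-open comparison reproduces the
acceleration mechanism: the closed configuration has lower mean drag,
higher mean net thrust, and reaches a fixed intermediate speed in fewer
cycles, while the open configuration shows higher raw thrust — the
wake-interaction signature in which the opened tail strengthens the
thrust jet yet costs more drag than it gains.  The efficiency ordering
does not reproduce: in 2-D the closed swimmer is both faster and
cheaper, so its Froude efficiency is higher and its cost of transport
lower than the open configuration's, opposite to the 3-D result.
Back-computing from the 3-D deltas shows the open-fin economy advantage
requires the closed tail to raise expended power by tens of percent at
identical fin motion — a fan-loading effect on the fins themselves that
a horizontal-plane section cannot carry, since its fin loading is
nearly configuration-independent.  The acceptance suite asserts all
five orderings and therefore fails the efficiency/cost pair by design;
the three acceleration-side orderings are the robust desk-scale result.

Known limitations: no fin elasticity (fins are kinematically driven);
one degree of freedom (no pitch, yaw, heave, or turning); laminar flow
only; the 2-D analogue's absolute forces carry the diffuse-interface
bias described above and are meaningful in paired comparison, not in
newtons; printed 3-D percentage deltas are treated as sign-level
properties only.
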