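# Methods

`adfsi` analyses visceral perfusion in aortic dissection under two
cardiopulmonary-bypass cannulation routes — axillary only (AC, all pump flow
through the brachiocephalic trunk) and combined axillary–femoral (AFC, flow
split equally between the brachiocephalic trunk and the right common iliac
artery) — with a two-way coupled fluid–structure model of the dissected
aorta. This note records the model, its planar reduction, the numerical
choices, and what the verification suite does and does not establish.

## The physical model

A dissected aorta carries blood in two channels: the original true lumen and
the false lumen created by the intimal tear, separated by a mobile intimal
flap. Two openings connect them: a large primary entry tear (98.45 mm²) in
the proximal descending aorta and a small re-entry tear (3.73 mm²) at the
left common iliac artery. All branch outlets drain to one common pressure
(the experimental analogue is an open reservoir), the ascending aorta is
closed (cardiac arrest), and the pump holds a steady flow of 3–7 L/min.

The mechanism of interest: under AC the entire pump flow enters proximally
and faces the dissection mouth, where the false lumen — a nearly stagnant
pocket whose only drain is the small re-entry tear — recovers the oncoming
dynamic head while the true lumen keeps flowing and loses head to
acceleration and friction. The resulting false-minus-true pressure
difference ΔP = p_FL − p_TL loads the flap, which bows into the true lumen
and narrows the celiac (CA) and superior-mesenteric (SMA) ostia: visceral
malperfusion. Under AFC the distal feed supplies the true lumen from the
other end, ΔP collapses toward zero, and the flap barely moves. Collapse is
quantified by the normalized true-lumen area

    A* = 100 · A1 / A0  [%]

with A0 / A1 the undeformed / deformed true-lumen cross-section at a branch
station.

## Planar reduction

The reference configuration is three-dimensional; this package computes on
a mid-plane planar analogue designed to preserve that mechanism at desk
cost. The reduction and its non-obvious choices:

- **Two-lumen channel.** A channel of height 24 mm (out-of-plane depth
  20 mm) is split over the dissected extent into a true lumen (bottom,
  11.5 mm, carrying the visceral ostia) and a false-lumen pocket (top)
  by the 1 mm flap strip. Unprinted dimensions (channel height, branch
  diameters 6–12 mm, segment lengths, stations) are anatomy-typical
  defaults, all overridable in `VesselSpec`.
- **Axial inflow.** The arch delivers flow axially into the descending
  aorta, so the brachiocephalic inflow enters through the proximal end
  face of the planar channel. (A top-wall inflow stub was tried and
  rejected: its wall-normal jet parks a recirculation pocket over the
  dissection mouth and feeds the false lumen artificially low pressure.)
- **Tear slots in the seal walls.** The false-lumen pocket is closed at
  both ends by rigid seal walls standing for the dissection shoulders
  where the flap rejoins the wall. Each tear becomes a vertical slot in a
  seal wall of height `area / depth` (4.92 mm entry, 0.19 mm re-entry),
  opening just above the flap. The entry slot thus faces the oncoming
  axial flow and receives its dynamic head, as the three-dimensional
  entry tear does at the dissection mouth; a lateral gap in the flap
  strip itself was tried first and sees Bernoulli suction instead — the
  flap then bows the wrong way.
- **Clamped flap.** The flap strip is clamped at both seals ("fixed
  support" on all non-wetted surfaces). The bookkeeping of the full
  three-dimensional tear geometry (elliptical semi-axes, stations) is
  retained in `VesselSpec`/`TearSpec` and drives the planar slot widths.
- **Area-preserving branch widths.** A circular branch of diameter D on an
  aorta of diameter H occupies an area fraction ≈ (D/H)²; a planar slot of
  width D would occupy D/H and badly over-conduct. Side branches are
  therefore meshed with slot width D²/H, which preserves the area fraction
  and with it the branch/aorta resistance balance that sets the flow
  split. The anatomical diameter remains the user-facing field.

## Fluid solver

Steady (or implicitly time-stepped, arbitrary Lagrangian–Eulerian)
incompressible Navier–Stokes with blood-analog properties ρ = 1060 kg/m³,
μ = 3.5 mPa·s, Newtonian. Discretization: Taylor–Hood triangles (quadratic
velocity, linear pressure) on block-masked rectilinear meshes, assembled
vectorized and solved by Newton iteration (a few Picard/Oseen sweeps first,
then full Newton; direct sparse factorization per step; pseudo-transient
continuation with a growing step as fallback). Because every Newton step
solves the linearized saddle system directly, discrete continuity holds to
machine precision at each iterate; global mass balance is limited only by
quadrature. Inflow is a flux-normalized Dirichlet profile (uniform with
wall taper by default, parabolic optional); every non-inlet branch is a
traction outlet at one common gauge pressure; walls and the flap interface
are no-slip. The nonlinear convergence tolerance defaults to 1e-3
(relative); Newton typically overshoots this by many orders.

**Desk-scale operating flows.** The nominal pump flows are applied through
a fixed `flow_scale = 0.06` (e.g. 7 L/min runs as 0.42 L/min, channel
Reynolds number ≈ 110). Two reasons: the planar model omits the reference
solver's turbulence closure, so it should stay cleanly laminar; and the
coarse (level-1) mesh supports spurious convected steady states above
roughly Re 250, verified by comparison against the next-finer mesh (branch
splits drift < 1% at the operating flows and diverge above ~0.5 L/min
effective inflow). The mechanism quantities scale with the dynamic head
but keep their orderings, which is what the qualitative acceptance checks
assert.

## Solid solver

Finite-strain, total-Lagrangian, plane-strain quadratic triangles for the
clamped flap (three element layers through the 1 mm thickness), Newton
iteration with adaptive load stepping and an element-inversion backtrack.
Two hyperelastic models:

- third-order **Ogden** in deviatoric principal stretches with the
  Shore-20A silicone constants μ = (−2025.7, −451.4, 1230.2) MPa,
  α = (−0.0706, −0.4271, −0.2728) (spectral stress evaluation);
- nearly incompressible **neo-Hookean**, ψ = μ/2 (Ī₁ − 3) + (1/d)(J − 1)²,
  with (μ, d) from (E, ν) via μ = E/(2(1+ν)), d = 2/K, K = E/(3(1−2ν)) —
  reproducing the printed pairs (0.2456 MPa, 0.164 /MPa) for E = 0.732 MPa
  and (0.0336 MPa, 1.2 /MPa) for E = 0.1 MPa at ν = 0.49.

The source constants treat the material as incompressible; since a
displacement-based solver needs a volumetric law, both models attach the
same (1/d)(J−1)² penalty with d derived from the model's own small-strain
shear modulus at ν = 0.49 (`ensure_volumetric`). The consistent tangent is
formed by directional finite differences of the analytic first
Piola–Kirchhoff stress; the spectral (Ogden) and invariant (neo-Hookean)
stress routes are cross-checked against each other and against
extended-precision energy differentiation in the tests.

A known inconsistency in the source constants is reported, not resolved:
the Ogden fit implies a small-strain shear modulus ½ Σ μₚαₚ ≈ 0.104 MPa
while the Shore-20A estimate E = 0.732 MPa implies μ ≈ 0.246 MPa (factor
≈ 2.4). `small_strain_shear_modulus` warns when a supplied target differs
by more than 2×. The flap density is never stated; 1100 kg/m³ (typical
silicone) is the default, and the steady results are density-independent.

## Coupling

Partitioned Dirichlet–Neumann: fluid solve on the deformed mesh → traction
transfer σ_f·n (with n the solid's outward normal) onto both flap surfaces
→ static flap solve → Aitken-relaxed interface-displacement update, until
the interface RMS residual (normalized by max(|d|, flap thickness)) falls
below 0.01. Aitken relaxation is on by default because a fixed
under-relaxation factor of 1.0 need not converge for the soft flap; the
fixed-factor mode is available for fidelity runs. The default path iterates
steady flow against static equilibrium (pseudo-transient continuation to
the stationary coupled state); the literal transient loop (Δt = 0.2 ms, end
time 2 s, 1–5 coupling sub-iterations per step) is implemented as a
fidelity option but is quasi-static per step for this light flap and much
more expensive — the packaged tests only smoke-test it.

Mesh motion is a per-column vertical stretch of each lumen between its
fixed wall and the displaced flap surface: interface nodes land exactly on
the solid surface (kinematic compatibility to 1e-9 mm, asserted in tests),
and the map cannot tangle before the gap guard trips. The guard limits
flap approach to 5% of the local lumen height and flags such runs
"collapse-limited"; it does not trip at the defaults.

## Verification and what it shows

- Plane Poiseuille: pressure drop within 2% of 12μLQ/(wh³) (in practice
  ~1e-9), parabolic profile exact.
- Manufactured solution (divergence-free streamfunction forcing): velocity
  L2 error converges at order ≈ 3 (contract: ≥ 2).
- Symmetric two-outlet junction: 50/50 split within 1%.
- Clamped strip under uniform pressure: midspan deflection within 5% of
  qL⁴/(384 E′I), tenfold stiffness → tenth deflection.
- Backward-Euler dynamics relax to the static solution within 1% by 2 s
  under constant load; free-vibration period scales as √(ρ/E).
- Near-rigid flap (E = 1000 MPa): coupled branch flows match a pure-CFD
  solve on the undeformed mesh within 1%.
- Mesh independence: branch splits drift < 2% between the two finest
  packaged levels at the operating flow.
- Replica audit: the packaged flow table reproduces the derived percent
  increases (96/133% visceral, 87/103% left iliac) and pressure
  differences (4.50 / 0.57 mmHg) by exact arithmetic; row mass-balance
  sums are reported verbatim, including the rows of the printed table that
  do not balance (see the flag layer in `data/flags.json`).

Passing these establishes that the solvers are correct on their analytic
anchors and that the planar model reproduces the *orderings* of the
reference findings — ΔP(CA) grows with AC flow while A*(CA) falls
(94.8 → 88.7% over 3–7 L/min at desk scale), AFC yields smaller ΔP and
larger A* than AC at every matched flow, a softer flap (E = 0.1 MPa)
collapses further than the stiff one, and AFC more than doubles
celiac outflow. It does not establish quantitative agreement with the
three-dimensional turbulent reference values (its absolute ΔP are ~mmHg,
ours ~0.01 mmHg at scaled flows), nor anything about pulsatile flow,
vessel-wall compliance, contact of a fully collapsed flap, or residual
stress — all outside the model by construction.

## Degenerate inputs and tie-breaks

Zero tear semi-axis gives a zero-area tear (meshing then fails loudly if a
slot has zero width). Zero inflow returns the exact rest state. ν = 0.5 is
accepted only as the strict-incompressibility limit d = 0 (warned); ν
beyond 0.5 is rejected. Non-converged coupled results are flagged and
refused by the post-processing accessors unless forced. The boundary-edge
orientation convention (counter-clockwise around the fluid domain) fixes
all normal signs; interface pairs are matched by sorted mid-node station.
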