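# Methods

This note documents the model, the numerical choices, and what the
synthetic-data studies do and do not establish.

## Multibody model

The rider is sagittal-plane only. The pelvis center and the crank axis are
fixed in space (seated pedaling on a stationary ergometer), so the
generalized coordinates are seven angles: hip, knee and ankle of each leg
plus the crank. Hip and knee are flexion-positive (hip measured from the
downward vertical), ankle is dorsiflexion-positive, and the crank is zero
with the left pedal at top dead center, positive rotation carrying the
pedal through the anterior side on the downstroke. Both hip joints share
one point (the planar projection of the two hips); segment inertial
parameters are standard proportional anthropometry for a ~67 kg, 1.70 m
rider and are fully overridable through the YAML config.

Equations of motion are assembled per leg from analytic point Jacobians
(M = Σ mᵀJᵀJ + I ggᵀ, bias from Jdot·qdot), verified against numerical
oracles: finite-difference Jacobians, mass-matrix symmetry/definiteness at
random postures, a compound-pendulum closed form, and a passive-swing
energy audit that conserves mechanical energy to 1e-6 relative over one
second with a high-accuracy explicit integrator. The crank row is
decoupled: its inertia is the lumped effective value I_eff = 23.53 kg·m²
(gear ratio 42/28 with a flywheel), its applied loads are the pedal-spring
torques and the resistive profile.

**Foot–pedal coupling.** Each foot is tied to its pedal by a point-to-point
spring (k = 1e5 N/m, rest length 0, damping 0 by default) at the distal
metatarsals. This "soft constraint" closes the kinematic loop without
algebraic constraints and doubles as the pedal-force sensor: the reaction
on the pedal is reported with anterior and upward components positive. A
1 mm stretch carries 100 N, so feasible solutions keep the feet within a
few millimeters of the pedals. The spring makes the ODEs stiff; the
forward simulator defaults to an implicit (Radau) integrator.

**Pedal angle.** The angle of the toe-to-heel line from the horizontal,
positive toe-down, reported in degrees with a +12.5° offset applied (the
convention used for the tracking targets). A pelvis tilt of 11.5° is the
default posture.

**Knee joint center.** A pure hinge by default. The config accepts
optional coupling polynomials (x/y offset of the knee center in the thigh
frame as functions of knee flexion) for models that translate the joint
center with flexion; the kinematics, Jacobians and bias terms handle the
coupling analytically, and the coefficients are left to the user because
no standard planar set exists.

## Muscle–tendon units

Each of the 18 MTUs is a three-component equilibrium Hill model. The
curve shapes are implementer-chosen, standard planar forms with all
constants in `MTUParams`:

* active force–length: Gaussian `exp(−((l/l_opt − 1)/w)²)`, width w = 0.25,
  negligible outside [0.4, 1.6]·l_opt (the NLP bounds CC lengths to this
  band);
* force–velocity: Hill hyperbola `(1+v)/(1−v/a)` for shortening
  (a = 0.25, v normalized by v_max = 10 l_opt/s) and a C¹ saturating
  eccentric branch with plateau 1.45;
* SEC and PEC: quadratic force–extension toes (C¹ at slack), the SEC
  reaching f_max at 4% tendon strain, the PEC at 60% CC stretch beyond
  optimal. A quadratic toe was preferred over an exponential one so the
  force is C¹ at slack, which the collocation Jacobians appreciate;
* excitation→activation: first order with τ_act = 15 ms, τ_deact = 60 ms;
* no pennation (a planar simplification).

Contraction dynamics invert the force–velocity curve for the CC velocity
that balances SEC force against active-plus-passive CC force. Where the
required force scale leaves the attainable range (below zero, or at the
eccentric plateau — e.g. an inactive muscle with a taut tendon), the
velocity is clamped to ±1 v_max and flagged in diagnostics; it is never a
silent NaN. The effective activation and force–length factors have small
floors (1e-3) so the inversion stays bounded.

Musculoskeletal geometry is polynomial: each MTU carries per-joint
moment-arm polynomials r(θ) (constant or low order, literature-scale
planar values), and MTU length is the reference length minus the integral
of the moment arms from a reference posture — so r = −∂l/∂θ holds exactly
by construction and is verified by finite differences at random postures.
Reference lengths are anchored mid-cycle (hip 0.8, knee 1.3, ankle
−0.1 rad) with the CC at optimal length and the SEC at slack.

## Crank load identification

The ergometer's resistive torque is not prescribed directly: it is
identified from crank data via the angular-momentum balance
T_resistive = T_crank − I_eff·α, with velocities and accelerations by
central differences, cycle-averaging onto angle bins, a periodic
moving-average smoother (window 5 of 72 bins), and resampling to 21
equally spaced points over [0°, 360°). The profile is indexed by crank
angle (it is cycle-periodic) and interpolated with a periodic cubic spline
(linear optional), applied as a generalized force on the crank DOF only,
opposing positive rotation.

## Synthetic targets and the cadence servo

The synthetic generator stands in for the experimental dataset. A rider
holds cadence on an ergometer, so the generator regulates the crank with a
servo torque toward a constant 360°/1.914 s ≈ 188 °/s while the legs are
driven either by phasic excitation bursts keyed to crank angle (muscle
mode; extensors on the downstroke, flexors and TA on the upstroke) or by a
computed-torque law tracking the pedal circle (torque mode). The servo is
not part of the collocation model, so after simulation the generator
*measures* the crank torque delivered through the pedals and re-identifies
the resistive profile from the momentum balance — exactly the procedure
used on experimental data. The identified profile absorbs the servo, so
the recorded cycle is dynamically near-consistent with the collocation
model that uses it; in torque mode the leg side is exactly consistent
because the applied joint torques are recorded as the controls.

Target SD bands emulate inter-subject spread as 5% of each variable's
range with floors of 1° (angles) and 5 N (forces); optional seeded
Gaussian noise (fraction of range) perturbs the means, default 0.
Bilateral symmetry mode replaces right-leg columns by the left leg shifted
180° of the cycle.

What passing recovery tests shows: the transcription, Jacobian coloring
and solver can recover a cycle that the model itself generated, with the
solution inside ±1 SD at every node. What it does not show: fidelity to
human data — the generator has no EMG, no inter-subject variability in
anthropometry, no measurement noise models, and its excitation bursts are
stylized.

## Transcription and solver

Backward-Euler defects (first-order, damped — adequate on the grids
studied and cheap per node), node-major decision ordering
[x₁,u₁,…,x_n,u_n] for a banded Jacobian, periodicity of 49 states + 18
controls plus the two pinned crank values (69 boundary rows grouped as
49+18+1+1). The activation integral is discretized as the mean of cubed
activations over nodes (÷ nMus·n); the dt-weighted alternative differs
only by the constant factor tFinal. Tracking targets are resampled to the
node grid by periodic linear interpolation when the sampling differs.

The constraint Jacobian uses forward differences with step
1e-6·(1+|z|) (central optional), grouped by a greedy
Curtis–Powell–Reid coloring of the hand-built sparsity pattern; grouped
and per-column differences agree exactly because group members share no
constraint rows. State bounds: configured angle boxes, ±30 rad/s
velocities, activations [0,1], CC lengths [0.4, 1.6]·l_opt; controls
[0,1] (excitations) or ±300 N·m (reduced mode).

Solving uses scipy: SLSQP by default with the analytic objective gradient
and the densified colored Jacobian, trust-constr (sparse) as an option;
feasibility tolerance 1e-6, and a solve may claim success only if the
largest constraint violation is below it. Far-from-feasible starts (the
static guess: constant posture while the crank ramps 0→360°, which
stretches the stiff springs badly) first pass through a
feasibility-restoration stage — bounded trust-region least squares on the
constraint residuals — before the SQP stage; with it, static- and
dynamic-guess solves of the same problem agree to many digits. The static
guess ramps the crank linearly (a literally constant crank angle cannot
satisfy both pinned end values) and uses the constant cycle-average crank
rate.

## Study problem sizes

The bundled studies run in the torque-actuated reduced mode (14 states, 6
joint-torque controls; effort = mean cubed torque normalized by 150 N·m)
on an 11-node grid, with the node-refinement comparison at 31 nodes, and
the full 18-muscle transcription exercised structurally at n = 11…181 and
through its forward simulator. These sizes keep each solve in the
tens-of-seconds range; the full-muscle tracking solve is the same code
path and scales with node count and the 68-column Jacobian band.

## Known limitations

* No 3-D pelvis motion, no non-seated cycling, no contact beyond the point
  springs.
* Muscle parameters are literature-style defaults, not calibrated to
  net/passive joint moments of any specific dataset; tests depend only on
  structural properties, not their magnitudes.
* Backward Euler is dissipative at coarse Δt; grid refinement (11→31
  nodes) measurably lowers the objective, mirroring the behaviour of the
  method class.
* The SQP solver is a dense-QP method; very fine grids (n ≥ 91) on the
  full model are slow and better served by an interior-point NLP solver
  through the same callback contract (objective, gradient, constraints,
  sparse Jacobian, structure).
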