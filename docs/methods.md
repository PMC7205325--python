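# Methods

## Neuron model and numerics

All dynamics use one discrete-time leaky-integrator rate neuron,
`v' = v + (−v + I_syn + I_app)/C_m`, updated at 1 ms with `C_m = 4.5`
(step units), output clipped to [0, 50] mV and per-sign synaptic sums
clipped at 80 mV. Internal voltages are *not* clipped, so recovery
dynamics below 0 mV remain representable; only the transmitted output is
bounded. Phasic units implement a nonlinear high-pass: the transmitted
value is `clip(input − baseline)` where the baseline tracks the input
with the slow constant (seconds) while the difference is positive and
with the fast constant (0.01 s) while it is negative. Networks are
updated synchronously (all units read previous-step outputs), which makes
every simulation a pure function of its configuration; repeated runs are
bit-identical. The body surrogate ticks at 10 ms with ten neural steps
per tick; sensor values are held constant between body ticks.

The per-leg architecture is represented twice: a declarative
`NetworkSpec` (unit/synapse tables used for structural checks, Dale's-law
verification, YAML/CSV export) and a scalar runtime evaluator built from
the same unit primitives. Purely combinational stages (NPPF error
signals, the binary ring-net layers) are evaluated algebraically at their
fixed points — with `C_m` = 4.5 ms against behavioral time scales of
hundreds of milliseconds the distinction is below the discretization
error — while every element whose *dynamics* carry meaning (motivation
bistables, premotor stages, phasic units, rule filters) is integrated at
1 ms.

## Single-leg control

Joint position sensors map linearly onto [0, 50] mV (antagonistic pairs
are the value and its 50-complement). Leg-level thresholds are defined on
the *oriented* alpha position `p` (the raw sensor for forward walking,
its mirror for backward walking), so one parameter set serves both
directions; the motor-neuron mapping of the alpha and gamma branches is
exchanged between the two.

Swing: alpha and gamma are position-controlled toward set points beyond
the nominal AEP with a feedforward floor, so swing velocity is
approximately constant until the error vanishes. The beta branch is
"disturbed" by a phasic levation pulse (amplitude 30 mV, decay 0.3 s)
whose peak is independent of the starting level and which is scaled down
at low velocities (short steps). The swing set point of beta sits 4 mV
*below* the stance level: the leg descends through ground level with
finite velocity, so touchdown produces a crisp load signal instead of an
asymptotic approach. A swinging leg that is pressed into the ground but
cannot yet hand over to stance re-drives its levator and keeps its
protractor inhibited (it lifts vertically instead of sliding).

Stance: alpha/gamma velocities come from the ring net (winning 15°
sector; retractor = 0.2·vel·sin, gamma = 0.2·vel·|cos| routed to
extensor for sectors 1–6 and flexor for 7–12; flexion drive saturates
above a 35 mV gamma sensor). Beta holds the height-net set point,
`B_nom / (1 + 0.5·|γ − γ_ref|/50)` — divisive normalization in the
deviation of the gamma sensor from the vertical-tibia reference, so a
tibia tilted *either* way (which shortens the effective leg) lowers the
set point. A 2 mV tonic depressor bias keeps the foot pressed to the
ground; the height equilibrium therefore sits slightly below the nominal
set point and body height is regulated leg-locally.

Transitions: swing→stance on ground load above 3 mV (torque proxy) once
the leg has passed the position gate *and* has been unloaded at least
once since swing onset (otherwise a leg released into swing while still
loaded would bounce straight back), or at the anterior limit (the
overridden curve AEP where applicable). Stance→swing when coordination
excitation overcomes the stance hold — which decays linearly from 14 mV
toward the posterior extreme — or unconditionally at the hard PEP, so an
isolated leg still steps. Both termination conditions also feed the
stance side of the bistable for a short time after the flip; without
this the mutual-inhibition race can chatter against sustained
coordination excitation.

The motivation bistable uses a tonic 25 mV drive to both units and
mutual inhibition of weight 1.2: the active unit is self-sustaining at
zero extra drive (short-term memory), and a competing drive must exceed
roughly `1.2·hold + 5` mV to flip the state (hysteresis).

## Premotor stage and intrinsic oscillation

Each joint's output stage is a four-unit network: two premotor units
whose adapting inhibitory interneurons inhibit the respective antagonist.
Fictive "pilocarpine" inputs pass a 25 mV threshold and drive both
branches. Adaptation constants 2.4 s / 1.35 s (depressor/levator side of
the beta joint) yield, in the fully coupled six-leg network, a ≈ 5.3 s
rhythm with a ≈ 2:1 depressor:levator duty ratio. The retractor–
protractor stage oscillates independently and adapts faster (1.1 s /
0.8 s); its intrinsic cycle (≈ 2.6 s) is what allows a single walking
leg at 30 mV to entrain the deafferented chain 1:1 in the treadmill
protocol.

## Rule-5 send/relay layer

Three design choices make the premotor coupling reproduce the
deafferented-preparation phenomenology:

1. **Saturating send units with a relay.** Each leg's "output 5" unit
   fires when its stance premotor signal exceeds 18 mV (well above
   normal-walking levels of ≈ 6–10 mV) and saturates at 50 mV; a leg
   without intrinsic activation relays its strongest neighbor's unit
   (×0.8 ipsilateral, ×0.2 contralateral, saturating selection). This
   lets a rhythm generated in one treated ganglion appear, attenuated,
   in every untreated hemiganglion.
2. **Phasic send dynamics.** The in-phase send signal passes a high-pass
   with a 3 s decay: coupling acts at burst onsets and cannot latch the
   mutually excitatory network into a static all-depressor state. The
   hind-leg 5ch channel uses the same filtered signal; with the
   quasi-tonic 3 s constant its mutual inhibition locks the hind pair at
   exactly half-cycle when it is the only coupling (metathorax-only
   treatment) yet is overridden by the stronger in-phase network when
   all ganglia are driven.
3. **Stance gating on both ends.** Send units carry a stance/load
   signal — a swinging leg's depressor (which pulls the leg down) is not
   broadcast — and incoming rule-5 influence only takes effect in legs
   that are not executing self-paced locomotion (deafferented or
   mechanically held); in an undisturbed walking leg it stays
   subthreshold relative to the sensory drives. Together these realize
   the observation that rule 5 is silent during undisturbed walking.

A treadmill-walking sender multiplies its premotor signal by the
friction factor (15) while its alpha sensor indicates the first half of
stance; the boosted value is transmitted without the send-unit
saturation, producing the strong periodic forcing that entrains the
pilocarpine-driven chain to the walking leg's period.

## Coordination-rule parameterization

Rules 1–3 are position/state driven and are therefore not emitted by
deafferented legs. The 2i channel is a velocity-gated charger (membrane
constant 0.6 s) feeding two cascaded 0.5 s high-pass stages; its drive
saturates in velocity (half-saturation 5 mV), so the pulse is strong
across the whole tested range while its threshold-crossing latency still
shrinks with velocity. The rule-3 windows shift linearly with velocity.
The numeric thresholds (see `params.py`) were chosen so that the
ipsilateral wave lag settles near one swing duration plus the 2i
latency, the 2i pulse from the rear neighbor and the 3i window from the
front neighbor coincide at the middle leg, and the contralateral rules
hold the two body sides apart.

## Body surrogate

The body is quasi-static and kinematic: no inertia, flat ground,
orthogonal joint axes, identical segment lengths (coxa 0.05 m, femur
0.36 m, tibia 0.40 m at a ≈ 1 m body length). Stance feet of normally
walking legs are anchored in the world; planar body velocity and yaw
rate are the least-squares consensus of the foot velocities implied by
their commanded joint rates, body height integrates the mean implied
vertical rate, and anchored joint angles are recovered by closed-form
inverse kinematics (no slip by construction; mechanically held legs may
slip when their anchor leaves the workspace). Motors integrate commanded
velocity into a desired angle with a bounded elastic deflection (±5 mV)
and a 0.6 s wind-up relaxation; `k·(desired − actual)` is the torque
proxy, with beta-spring constants 8.5:4.5:8.5 (front:middle:hind). A
free joint tracks its desired angle directly — the elastic element shows
only under constraint, which keeps the load signal free of
velocity-proportional artifacts.

## Protocols and problem sizes

Forward/backward runs use 80 s (300 s at 8 mV, where the stable pattern
forms slowly), curve walking 100 s with the printed parameter set
(45 mV, θ-code 5 for the inner front leg and 1 for the outer, AEP set
points 20/20 and 50/45 mV, velocity factors 1 / 0.75 / 0.35 / 0.1), and
the deafferentation protocols 60–90 s. The pilocarpine onset is
staggered by 0.25 s per leg in a fixed order, emulating gradual
perfusion; this deterministic asymmetry lets the network select its
phase-locking attractor (identical initial states would sit on the
unstable symmetric manifold forever). The only random element anywhere
is optional start-posture jitter, driven by an explicit seed.

## What the surrogate does and does not show

Passing tests demonstrate that the *control architecture* produces the
emergent gait continuum, curve and backward walking, stopping behavior,
and the deafferented-preparation rhythms, under an idealized body: no
inertia, perfect ground contact, noiseless sensors. They do not
constrain trajectory-level agreement with a dynamic robot or with animal
kinematics (leg-tip trajectories, absolute forces); those comparisons
are qualitative by design. Known limitations: the contralateral
phase locks near 0.5 at all velocities, so the paired ("mirror-image")
tetrapod with phases ≈ 1/3 and 2/3 does not form — the disturbance
protocol returns the walker to the same symmetric pattern; the inner
front leg steps without ground contact during tight curve walking; and
the standing-leg experiments reproduce burst timing but not calibrated
forces (the retractor motor-neuron output serves as the force proxy).
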