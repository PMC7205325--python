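# neurohex

A decentralized artificial-neural-network controller for hexapod walking,
together with a simplified kinematic body surrogate and the experimental
protocols needed to study it. The package is aimed at computational
neuroscientists and roboticists interested in how insect-like walking —
the velocity-dependent gait continuum, curve negotiation, backward
walking, and the intrinsic rhythms seen in deafferented preparations —
can emerge from purely local control without a central gait clock.

## The model

Every unit is a leaky-integrator rate neuron updated at 1 ms,

    v[t+1] = v[t] + (−v[t] + I_syn + I_app) / C_m ,     C_m = 4.5 ms

with a piecewise-linear output clipped to [0, 50] mV; excitatory and
inhibitory synaptic sums are clipped separately at 80 mV, every unit is
either excitatory or inhibitory (Dale's law), and selected units carry a
phasic (high-pass) characteristic with asymmetric time constants (slow
decay ≈ seconds, fast recovery 0.01 s).

Each of the six legs runs an identical controller:

* **swing–stance and forward–backward motivation units** — mutual-
  inhibition bistables acting as short-term memory of the behavioral
  state;
* **antagonistic joint branches** (protractor/retractor, levator/
  depressor, flexor/extensor) — negative proportional position feedback
  (NPPF) during swing, velocity control during stance;
* a **height net** that maps the gamma angle onto the stance set point of
  the beta joint via divisive normalization;
* a **ring net** (5 layers × 12 units, 15° sectors) that converts the
  desired walking direction θ and the current alpha position into stance
  velocity components: spatial code = ⌈α*/(50/12)⌉ − θ with
  α* = (α + 50)/3, and output weights 0.2·sin / 0.2·cos of the winning
  sector;
* a **premotor stage** per joint: antagonistic premotor units coupled by
  adapting inhibitory interneurons. With tonic drive ≥ 25 mV on *both*
  branches (the pilocarpine condition) the stage becomes a relaxation
  oscillator with a ≈ 5 s period and a 2:1 depressor:levator duty ratio;
  during normal walking it simply relays the sensory drives.

Legs interact only through local **coordination rules** between direct
neighbors: rule 1 (rear→front swing inhibition, with a 1b delay
integrator), rule 2i (phasic swing excitation after the sender's swing
end, later and weaker at low velocity), rule 3i (position-window
excitation front→rear), rules 2c/3c (contralateral), and rule 5
(premotor-level load coupling, gain 0.2 ipsilateral / 0.1 contralateral,
with the hind-leg pair carrying the sign-inverted 5ch channel). Gaits are
never programmed: tripod, tetrapod and pentapod patterns emerge from the
interplay of these rules with the body.

The body surrogate is quasi-static: stance feet are anchored in the
world, body motion is the least-squares consensus of the commanded foot
velocities, and each motor's elastic element provides a torque/load proxy
used to terminate swing on ground contact.

## Worked example

```python
from neurohex import protocols, gait_analysis

cfg = protocols.ExperimentConfig(protocol="forward", velocity_mV=50.0,
                                 duration_s=80.0)
trace = protocols.run_protocol(cfg).trace
ft = gait_analysis.extract_footfall(trace, window=(20.0, 80.0))
gm = gait_analysis.classify_gait(ft)
print(gm.label, gm.min_stance_count)
print(round(gm.period_s["FL"], 2),
      round(gm.contralateral_phase["FL-FR"], 2))
```

prints

    tripod 3
    2.21 0.51

i.e. at a velocity-neuron setting of 50 mV the walker settles into a
tripod pattern (at least three legs grounded at every instant), with a
2.2 s step period and front legs in anti-phase (contralateral phase
0.51 ≈ 0.5). At 20 mV the same code reports a tetrapod (min stance 4)
and at 8 mV a pentapod (min stance 5) — the continuum emerges from the
velocity input alone.

The same API runs the neurophysiology protocols
(`protocols.configure_pilocarpine`, `configure_treadmill_single_leg`,
`configure_standing_legs`) and backward/curve walking; a thin CLI wraps
it: `neurohex run --protocol forward --velocity 30 --duration 80
--out trace.csv` and `neurohex analyze trace.csv`.

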