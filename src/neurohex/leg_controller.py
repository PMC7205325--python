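"""Single-leg controller.

Each leg runs an identical controller built from rate neurons:

* two bistable motivation pairs (swing-stance and forward-backward), each
  a mutual-inhibition "monopole" acting as short-term memory of the
  behavioral state;
* six antagonistic joint branches (protractor/retractor for the alpha
  joint, levator/depressor for beta, flexor/extensor for gamma), each a
  negative proportional position-feedback (NPPF) controller during swing
  and - for alpha/gamma - a velocity channel fed by the ring net during
  stance;
* a height net that turns the gamma angle into the stance set point of the
  beta branch via divisive normalization;
* a phasic "disturb" unit that briefly drives the levator at swing onset
  so the leg lifts by a constant amount independent of its start level,
  scaled down at very low velocities (short steps);
* a premotor/motor output stage per joint: antagonistic premotor units
  coupled through adapting inhibitory interneurons (recurrent lateral
  inhibition).  With only one branch driven the stage simply relays its
  drive; with both branches tonically driven (the pilocarpine condition)
  the adaptation turns the stage into a slow relaxation oscillator.

State transitions are not scripted: swing ends on ground load (past a
position gate) or at the anterior limit; stance ends when coordination
excitation overcomes the position-dependent decay of the stance
motivation, or at the posterior limit, so a fully isolated leg still
steps on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import ring_net
from .neuron_core import (
    BasicUnit,
    HighpassUnit,
    NetworkSpec,
    SynapseSpec,
    UnitSpec,
    V_MAX,
)
from .params import ControllerParams, default_params

LEG_IDS = ("FL", "FR", "ML", "MR", "HL", "HR")

# branch naming: side "A" carries the rule-5 coupled muscle of each joint
BRANCHES = {
    "alpha": ("ret", "pro"),
    "beta": ("dep", "lev"),
    "gamma": ("flex", "ext"),
}


@dataclass
class SensorFrame:
    """Sensor values delivered once per body tick (held between ticks)."""

    alpha: float = 25.0   # protractor-direction position sensor, mV
    beta: float = 18.0    # levator-direction position sensor, mV
    gamma: float = 32.0   # flexion-direction position sensor, mV
    load: float = 0.0     # beta torque proxy, mV
    contact: bool = False
    touch: bool = False   # obstacle touch during swing


@dataclass
class CoordIn:
    """Aggregated coordination input for one leg at one neural tick."""

    swing_exc: float = 0.0            # rules 2i, 3i, 2c, 3c
    swing_inh: float = 0.0            # rules 1a, 1b
    pmn_add: Dict[Tuple[str, str], float] = field(default_factory=dict)
    # rule 5: signed additions keyed by (joint, branch), e.g. ("alpha","ret")


@dataclass
class MotivationState:
    swing_act: float = 0.0
    stance_act: float = 0.0
    forward_act: float = 0.0
    backward_act: float = 0.0


@dataclass
class JointBranch:
    joint: str
    side: str
    set_point: float = 0.0
    sensor: float = 0.0
    error: float = 0.0
    premotor: float = 0.0
    motor: float = 0.0


@dataclass
class LegControllerState:
    """Snapshot of one leg's controller, streamed to the trace."""

    leg_id: str
    mode: str = "stance"
    direction: str = "forward"
    motivation: MotivationState = field(default_factory=MotivationState)
    branches: List[JointBranch] = field(default_factory=list)
    oriented_p: float = 25.0


def height_net_eval(gamma_sensor: float,
                    params: Optional[ControllerParams] = None) -> float:
    """Stance beta set point as a function of the gamma (flexion) sensor.

    Divisive normalization: the nominal set point is scaled by a smooth
    multiplicative factor 1 / (1 + g * |gamma - gamma_ref|/50).  At the
    vertical-tibia reference the factor is 1; a tibia tilted away from
    vertical in either direction shortens the effective leg, so the beta
    set point falls (more depression) to keep body height constant.
    """
    p = params or _DEFAULTS
    st = p.stance
    if not 0.0 <= gamma_sensor <= 50.0:
        raise ValueError(f"gamma sensor out of range: {gamma_sensor}")
    g = 1.0 / (1.0 + st.height_gain * abs(gamma_sensor - st.gamma_ref) / 50.0)
    return max(0.0, min(V_MAX, st.beta_set_nominal * g))


_DEFAULTS = default_params()


class MotivationPair:
    """Bistable monopole: two units with mutual inhibition + tonic drive."""

    def __init__(self, p: ControllerParams, active: str = "stance") -> None:
        m = p.motivation
        self.tonic = m.tonic
        self.w = m.w_mutual
        self.a = BasicUnit(Cm=m.Cm, v0=m.tonic if active == "swing" else 0.0)
        self.b = BasicUnit(Cm=m.Cm, v0=m.tonic if active == "stance" else 0.0)

    def step(self, drive_a: float, drive_b: float) -> Tuple[float, float]:
        ia = self.tonic + max(0.0, drive_a) - self.w * self.b.output
        ib = self.tonic + max(0.0, drive_b) - self.w * self.a.output
        self.a.step(ia)
        self.b.step(ib)
        return self.a.output, self.b.output


def motivation_step(pair: MotivationPair, swing_drive: float,
                    stance_drive: float) -> MotivationState:
    """One update of the swing-stance bistable; returns the new activations."""
    if swing_drive < 0 or stance_drive < 0:
        raise ValueError("motivation drives must be >= 0")
    sw, st = pair.step(swing_drive, stance_drive)
    return MotivationState(swing_act=sw, stance_act=st)


class PremotorStage:
    """Four-unit recurrent-inhibition output stage for one joint.

    PMN_a and PMN_b are the antagonistic premotor units; each excites an
    inhibitory interneuron with high-pass (adapting) dynamics that
    inhibits the opposite PMN.  Motor units relay the PMN outputs.
    """

    __slots__ = ("p", "pmn_a", "pmn_b", "inh_a", "inh_b", "mn_a", "mn_b")

    def __init__(self, p: ControllerParams, joint: str = "beta") -> None:
        pm = p.premotor
        self.p = pm
        self.pmn_a = BasicUnit(Cm=pm.Cm)
        self.pmn_b = BasicUnit(Cm=pm.Cm)
        # the retractor-protractor stage oscillates independently of the
        # levator-depressor stage and adapts somewhat faster
        if joint == "alpha":
            ta, tb = pm.tau_adapt_alpha_a, pm.tau_adapt_alpha_b
        else:
            ta, tb = pm.tau_adapt_a, pm.tau_adapt_b
        self.inh_a = HighpassUnit(tau_fall=ta)
        self.inh_b = HighpassUnit(tau_fall=tb)
        self.mn_a = BasicUnit(Cm=pm.Cm)
        self.mn_b = BasicUnit(Cm=pm.Cm)

    def step(self, drive_a: float, drive_b: float,
             pilo_a: float = 0.0, pilo_b: float = 0.0,
             add_a: float = 0.0, add_b: float = 0.0,
             gate_a: float = 1.0, gate_b: float = 1.0) -> Tuple[float, float]:
        pm = self.p
        pa = pilo_a if pilo_a >= pm.pilo_threshold else 0.0
        pb = pilo_b if pilo_b >= pm.pilo_threshold else 0.0
        ia = drive_a + pa + add_a - pm.w_inh_to_pmn * self.inh_b.output
        ib = drive_b + pb + add_b - pm.w_inh_to_pmn * self.inh_a.output
        self.pmn_a.step(ia)
        self.pmn_b.step(ib)
        self.inh_a.step(pm.w_pmn_to_inh * self.pmn_a.output)
        self.inh_b.step(pm.w_pmn_to_inh * self.pmn_b.output)
        self.mn_a.step(self.pmn_a.output * gate_a)
        self.mn_b.step(self.pmn_b.output * gate_b)
        return self.mn_a.output, self.mn_b.output


class LegController:
    """Runtime controller for one leg (see module docstring)."""

    def __init__(self, leg_id: str,
                 params: Optional[ControllerParams] = None,
                 direction: str = "forward",
                 start_mode: str = "stance") -> None:
        if leg_id not in LEG_IDS:
            raise ValueError(f"unknown leg id {leg_id!r}")
        self.leg_id = leg_id
        self.p = params or default_params()
        self.direction = direction
        self.motiv = MotivationPair(self.p, active=start_mode)
        self.mode = start_mode
        self.dir_pair = MotivationPair(
            self.p, active="swing" if direction == "backward" else "stance"
        )  # a=backward, b=forward
        self.stages: Dict[str, PremotorStage] = {
            j: PremotorStage(self.p, joint=j)
            for j in ("alpha", "beta", "gamma")
        }
        self.pulse = HighpassUnit(tau_fall=self.p.swing.pulse_tau)
        self.touch_hpf = HighpassUnit(tau_fall=self.p.swing.touch_tau)
        # leg-local command state
        self.vel_local = 0.0          # leg-local stance velocity, mV
        self.theta_code = 0           # local walking-direction code
        self.swing_target_alpha: Optional[float] = None  # curve AEP override
        self.swing_target_gamma: Optional[float] = None
        self.pilo: Dict[str, Tuple[float, float]] = {}
        self.deafferented = False
        self.standing = False         # intact but mechanically held
        self.force_swing = False      # disturbance: hold swing artificially
        self.force_stance = False     # deafferented legs are held in stance
        self.gate_passed = False      # position gate during current swing
        self.lifted = False           # leg unloaded since swing onset
        # last outputs, keyed (joint, branch)
        self.mn_out: Dict[Tuple[str, str], float] = {
            (j, s): 0.0 for j in BRANCHES for j_s in [BRANCHES[j]] for s in j_s
        }
        self.pmn_out: Dict[Tuple[str, str], float] = dict(self.mn_out)

    # -- helpers ----------------------------------------------------------

    def oriented_p(self, alpha: float) -> float:
        return alpha if self.direction == "forward" else 50.0 - alpha

    def _fwd_branch(self) -> Tuple[str, str]:
        """(progressing, regressing) alpha branches for the current direction.

        The progressing branch moves the leg toward its swing target: the
        protractor when walking forward, the retractor when walking
        backward (MN mapping is reversed between the two directions).
        """
        if self.direction == "forward":
            return "pro", "ret"
        return "ret", "pro"

    # -- drives -----------------------------------------------------------

    def swing_drives(self, sens: SensorFrame) -> Dict[Tuple[str, str], float]:
        """Branch drives while the swing motivation is active."""
        sw = self.p.swing
        st = self.p.stance
        p = self.oriented_p(sens.alpha)
        prog, reg = self._fwd_branch()
        drives = {(j, s): 0.0 for j in BRANCHES for s in BRANCHES[j]}

        target = sw.target_p
        if self.swing_target_alpha is not None:
            target = self.oriented_p(self.swing_target_alpha)
        err = max(target - p, 0.0)
        if err > sw.err_eps:
            drives[("alpha", prog)] = min(sw.cap, max(sw.kp * err, sw.floor))
        else:
            drives[("alpha", prog)] = min(sw.cap, sw.kp * err)

        g_target = (self.swing_target_gamma
                    if self.swing_target_gamma is not None
                    else sw.gamma_target)
        g_err = g_target - sens.gamma
        g_drive = (min(sw.cap, max(sw.kp * abs(g_err), 0.5 * sw.floor))
                   if abs(g_err) > sw.err_eps else sw.kp * abs(g_err))
        if g_err > 0:
            drives[("gamma", "flex")] = g_drive
        else:
            drives[("gamma", "ext")] = g_drive

        # beta: NPPF around a set point slightly below the stance level
        # (the leg descends through ground level and lands with finite
        # velocity, so touchdown produces a crisp load signal), disturbed
        # by the levation pulse
        bset = height_net_eval(sens.gamma, self.p) - sw.descend_margin
        vel_scale = max(sw.short_step_min,
                        min(1.0, self.vel_local / sw.short_step_vel))
        pulse_in = (sw.pulse_amp * vel_scale
                    if self.motiv.a.output > 10.0 else 0.0)
        pulse_out = self.pulse.step(pulse_in)
        touch_out = self.touch_hpf.step(sw.touch_amp if sens.touch else 0.0)
        drives[("beta", "lev")] = (
            self.p.stance.k_beta * max(bset - sens.beta, 0.0)
            + pulse_out + touch_out
        )
        drives[("beta", "dep")] = st.k_beta * max(sens.beta - bset, 0.0)
        # a swinging leg pressed into the ground that cannot yet hand
        # over to stance (position gate not passed) keeps driving its
        # levator until it clears; the protractor stays inhibited so the
        # leg lifts vertically instead of sliding
        if (sens.contact and sens.load > st.load_threshold
                and not (self.gate_passed and self.lifted)):
            drives[("beta", "lev")] += 8.0
            drives[("beta", "dep")] = 0.0
        # levator reflex: brief retraction accompanies the levation
        if touch_out > 1.0:
            drives[("alpha", reg)] += 0.5 * touch_out
        return drives

    def stance_drives(self, sens: SensorFrame) -> Dict[Tuple[str, str], float]:
        """Branch drives while the stance motivation is active."""
        st = self.p.stance
        drives = {(j, s): 0.0 for j in BRANCHES for s in BRANCHES[j]}
        self.pulse.step(0.0)
        self.touch_hpf.step(0.0)
        out = ring_net.evaluate(sens.alpha, self.theta_code, self.vel_local)
        md = ring_net.route_to_joints(out, "stance", self.direction,
                                      gamma_sensor=sens.gamma)
        drives[("alpha", "pro")] = md.protractor
        drives[("alpha", "ret")] = md.retractor
        drives[("gamma", "flex")] = md.flexor
        drives[("gamma", "ext")] = md.extensor
        bset = height_net_eval(sens.gamma, self.p)
        drives[("beta", "lev")] = st.k_beta * max(bset - sens.beta, 0.0)
        # tonic depressor bias keeps the foot pressed to the ground; the
        # height equilibrium sits just below the nominal set point
        drives[("beta", "dep")] = (st.k_beta * max(sens.beta - bset, 0.0)
                                   + st.press_bias)
        return drives

    # -- phase transitions -------------------------------------------------

    def _swing_end_p(self) -> float:
        """Anterior position terminating swing (overridden AEP for curves)."""
        sw = self.p.swing
        if self.swing_target_alpha is None:
            return sw.end_p
        return self.oriented_p(self.swing_target_alpha) - 2.0

    def transition_drives(self, sens: SensorFrame,
                          coord: CoordIn) -> Tuple[float, float]:
        """(swing_drive, stance_drive) for the motivation bistable."""
        m = self.p.motivation
        sw = self.p.swing
        st = self.p.stance
        p = self.oriented_p(sens.alpha)
        end_p = self._swing_end_p()
        swing_drive = 0.0
        stance_drive = 0.0
        if self.force_stance:
            return 0.0, m.load_trigger
        if self.force_swing:
            return m.pep_trigger + 20.0, 0.0
        if self.mode == "stance":
            hold = st.hold_max * max(
                0.0, min(1.0, (p - st.p_min) / (st.hold_hi_p - st.p_min))
            )
            stance_drive = hold
            # the swing-termination conditions keep supporting stance
            # just after the transition, so the bistable race cannot
            # chatter while coordination excitation is still present
            if p >= end_p:
                stance_drive += m.aep_trigger
            if (sens.contact and sens.load > st.load_threshold
                    and p >= sw.gate_p + 10.0):
                stance_drive += m.load_trigger
            exc = coord.swing_exc
            if p <= st.p_min:
                exc += m.pep_trigger
            swing_drive = max(0.0, exc - coord.swing_inh)
        else:
            self.gate_passed = self.gate_passed or p >= sw.gate_p
            self.lifted = (self.lifted
                           or sens.load < 0.5 * st.load_threshold
                           or not sens.contact)
            if (sens.load > st.load_threshold and self.gate_passed
                    and self.lifted):
                stance_drive += m.load_trigger
            if p >= end_p:
                stance_drive += m.aep_trigger
            swing_drive = max(0.0, coord.swing_exc - coord.swing_inh)
        return swing_drive, stance_drive

    def phase_transition_check(self, sens: SensorFrame,
                               coord: CoordIn) -> str:
        """Categorical view of the pending transition.

        Evaluates the same conditions that drive the motivation bistable
        (without stepping it) and reports ``"to_swing"``, ``"to_stance"``
        or ``"stay"``.
        """
        swing_drive, stance_drive = self.transition_drives(sens, coord)
        m = self.p.motivation
        if self.mode == "stance":
            hold = stance_drive
            if swing_drive > m.w_mutual * hold + 5.0:
                return "to_swing"
        else:
            if stance_drive > m.w_mutual * swing_drive + 5.0:
                return "to_stance"
        return "stay"

    # spec-facing aliases for the per-state drive computations
    def swing_controller_step(self, sens: SensorFrame):
        return self.swing_drives(sens)

    def stance_controller_step(self, sens: SensorFrame):
        return self.stance_drives(sens)

    # -- main update --------------------------------------------------------

    def neural_step(self, sens: SensorFrame, coord: CoordIn) -> None:
        """One 1 ms update of the whole leg controller."""
        swing_drive, stance_drive = self.transition_drives(sens, coord)
        sw_act, st_act = self.motiv.step(swing_drive, stance_drive)
        prev_mode = self.mode
        self.mode = "swing" if sw_act > st_act else "stance"
        if self.mode == "swing" and prev_mode == "stance":
            self.gate_passed = False
            self.lifted = False

        if self.mode == "swing":
            drives = self.swing_drives(sens)
        else:
            drives = self.stance_drives(sens)

        # protractor inhibited while in swing but still under load
        prog, _ = self._fwd_branch()
        gate_pro = 0.0 if (
            self.mode == "swing" and sens.contact
            and sens.load > self.p.stance.load_threshold
        ) else 1.0

        # incoming rule-5 influences only take effect in legs that are not
        # executing self-paced locomotion (deafferented or mechanically
        # held); in an undisturbed walking leg they stay subthreshold
        # relative to the sensory drives
        receive5 = self.deafferented or self.standing
        for joint in ("alpha", "beta", "gamma"):
            a_name, b_name = BRANCHES[joint]
            pa, pb = self.pilo.get(joint, (0.0, 0.0))
            add_a = coord.pmn_add.get((joint, a_name), 0.0) if receive5 else 0.0
            add_b = coord.pmn_add.get((joint, b_name), 0.0) if receive5 else 0.0
            ga = gate_pro if (joint, a_name) == ("alpha", "pro") else 1.0
            gb = gate_pro if (joint, b_name) == ("alpha", "pro") else 1.0
            stage = self.stages[joint]
            out_a, out_b = stage.step(
                drives[(joint, a_name)], drives[(joint, b_name)],
                pilo_a=pa, pilo_b=pb, add_a=add_a, add_b=add_b,
                gate_a=ga, gate_b=gb,
            )
            self.mn_out[(joint, a_name)] = out_a
            self.mn_out[(joint, b_name)] = out_b
            self.pmn_out[(joint, a_name)] = stage.pmn_a.output
            self.pmn_out[(joint, b_name)] = stage.pmn_b.output

    def joint_velocity_commands(self) -> Dict[str, float]:
        """Net commanded joint velocities in sensor-mV/s (sign: sensor up)."""
        mo = self.p.motor
        if self.deafferented:
            return {"alpha": 0.0, "beta": 0.0, "gamma": 0.0}
        return {
            "alpha": mo.gain_alpha * (self.mn_out[("alpha", "pro")]
                                      - self.mn_out[("alpha", "ret")]),
            "beta": mo.gain_beta * (self.mn_out[("beta", "lev")]
                                    - self.mn_out[("beta", "dep")]),
            "gamma": mo.gain_gamma * (self.mn_out[("gamma", "flex")]
                                      - self.mn_out[("gamma", "ext")]),
        }

    def snapshot(self, sens: SensorFrame) -> LegControllerState:
        st = LegControllerState(leg_id=self.leg_id, mode=self.mode,
                                direction=self.direction)
        st.motivation = MotivationState(
            swing_act=self.motiv.a.output, stance_act=self.motiv.b.output,
            backward_act=self.dir_pair.a.output,
            forward_act=self.dir_pair.b.output,
        )
        st.oriented_p = self.oriented_p(sens.alpha)
        for joint in BRANCHES:
            for side in BRANCHES[joint]:
                st.branches.append(JointBranch(
                    joint=joint, side=side,
                    sensor={"alpha": sens.alpha, "beta": sens.beta,
                            "gamma": sens.gamma}[joint],
                    premotor=self.pmn_out[(joint, side)],
                    motor=self.mn_out[(joint, side)],
                ))
        return st


# ---------------------------------------------------------------------------
# declarative network description (structure checks, census, export)
# ---------------------------------------------------------------------------

def build_leg_controller(
    leg_id: str, params: Optional[ControllerParams] = None,
) -> Tuple[NetworkSpec, LegController]:
    """Assemble the declarative per-leg network and its runtime controller.

    The returned :class:`NetworkSpec` documents the unit/synapse structure
    (motivation bistables, six NPPF branches, height net, premotor stage,
    coordination send/receive units, ring net) and passes
    :func:`neuron_core.check_dale`; the :class:`LegController` executes the
    same architecture with scalar units.
    """
    p = params or default_params()
    units: List[UnitSpec] = []
    syn: List[SynapseSpec] = []
    L = leg_id

    def u(name: str, **kw) -> str:
        uid = f"{L}.{name}"
        units.append(UnitSpec(id=uid, **kw))
        return uid

    vel = u("vel", sign="excitatory")
    sw = u("motiv.swing", sign="inhibitory")
    st = u("motiv.stance", sign="inhibitory")
    syn += [SynapseSpec(sw, st, p.motivation.w_mutual),
            SynapseSpec(st, sw, p.motivation.w_mutual)]
    bwd = u("motiv.backward", sign="inhibitory")
    fwd = u("motiv.forward", sign="inhibitory")
    syn += [SynapseSpec(bwd, fwd, p.motivation.w_mutual),
            SynapseSpec(fwd, bwd, p.motivation.w_mutual)]
    pulse = u("swing.disturb", kind="highpass", sign="excitatory",
              tau_fall=p.swing.pulse_tau)
    touch = u("swing.touch", kind="highpass", sign="excitatory",
              tau_fall=p.swing.touch_tau)
    syn.append(SynapseSpec(vel, pulse, 1.0))

    # height net: gamma sensor gates the set-point unit presynaptically
    hn_in = u("height.gamma_in", sign="excitatory")
    hn_mid = u("height.norm", sign="excitatory")
    hn_out = u("height.set_point", sign="excitatory")
    syn.append(SynapseSpec(hn_mid, hn_out, 1.0,
                           modulation="presynaptic_inhibition",
                           gate_unit=hn_in))

    for joint, (a_name, b_name) in BRANCHES.items():
        sens = u(f"{joint}.sensor_{a_name}", sign="excitatory")
        sens_b = u(f"{joint}.sensor_{b_name}", sign="inhibitory")
        for side in (a_name, b_name):
            sp = u(f"{joint}.{side}.set_point", sign="excitatory")
            err = u(f"{joint}.{side}.error", sign="excitatory")
            ff = u(f"{joint}.{side}.feedforward", sign="excitatory")
            pmn = u(f"{joint}.{side}.pmn", sign="excitatory")
            inh = u(f"{joint}.{side}.pmn_inh", kind="highpass",
                    sign="inhibitory",
                    tau_fall=(p.premotor.tau_adapt_a if side == a_name
                              else p.premotor.tau_adapt_b))
            mn = u(f"{joint}.{side}.mn", sign="excitatory")
            pilo = u(f"{joint}.{side}.pilo", sign="excitatory")
            syn += [
                SynapseSpec(sp, err, 1.0),
                SynapseSpec(sens_b, err, 0.02),  # subtractive sensory input
                SynapseSpec(err, pmn, 1.0),
                SynapseSpec(err, ff, 1.0),
                SynapseSpec(ff, pmn, 1.0),
                SynapseSpec(pilo, pmn, 1.0),
                SynapseSpec(pmn, inh, p.premotor.w_pmn_to_inh),
                SynapseSpec(pmn, mn, 1.0),
            ]
        # recurrent lateral inhibition between the antagonistic PMNs
        syn += [
            SynapseSpec(f"{L}.{joint}.{a_name}.pmn_inh",
                        f"{L}.{joint}.{b_name}.pmn",
                        p.premotor.w_inh_to_pmn),
            SynapseSpec(f"{L}.{joint}.{b_name}.pmn_inh",
                        f"{L}.{joint}.{a_name}.pmn",
                        p.premotor.w_inh_to_pmn),
        ]
        _ = sens
    syn.append(SynapseSpec(pulse, f"{L}.beta.lev.pmn", 1.0))
    syn.append(SynapseSpec(touch, f"{L}.beta.lev.pmn", 1.0))
    syn.append(SynapseSpec(hn_out, f"{L}.beta.dep.set_point", 1.0))
    syn.append(SynapseSpec(hn_out, f"{L}.beta.lev.set_point", 1.0))

    # ring net: 5 layers x 12 units plus the four output units
    prev_layer: List[str] = []
    for layer, (kind, sign) in enumerate([
        ("basic", "excitatory"), ("basic", "excitatory"),
        ("basic", "inhibitory"), ("basic", "excitatory"),
        ("basic", "excitatory"),
    ], start=1):
        layer_ids = [u(f"ring.l{layer}.c{j}", kind=kind, sign=sign)
                     for j in range(1, 13)]
        if layer in (2, 3):
            for a, b in zip(prev_layer, layer_ids):
                syn.append(SynapseSpec(a, b, 1.0))
        if layer in (4, 5):
            for j, b in enumerate(layer_ids, start=1):
                phi = math.radians(ring_net.sector_angle_deg(j))
                w = ring_net.GAIN * abs(
                    math.sin(phi) if layer == 4 else math.cos(phi))
                syn.append(SynapseSpec(vel, b, w))
                syn.append(SynapseSpec(
                    f"{L}.ring.l3.c{j}", b, 1.0))
        prev_layer = layer_ids
    o1 = u("ring.O1", sign="excitatory")
    o2 = u("ring.O2", sign="excitatory")
    o3 = u("ring.O3", sign="excitatory")
    o4 = u("ring.O4", sign="excitatory")
    for j in range(1, 13):
        syn.append(SynapseSpec(f"{L}.ring.l4.c{j}", o2, 1.0))
        target = o4 if j <= 6 else o3
        syn.append(SynapseSpec(f"{L}.ring.l5.c{j}", target, 1.0))
    syn.append(SynapseSpec(o2, f"{L}.alpha.ret.pmn", 1.0))
    syn.append(SynapseSpec(o3, f"{L}.gamma.flex.pmn", 1.0))
    syn.append(SynapseSpec(o4, f"{L}.gamma.ext.pmn", 1.0))
    _ = o1  # present but not connected (tight turns only)

    # coordination send/receive relay units
    for rule in ("1a", "1b", "2i", "3i", "2c", "3c"):
        u(f"coord.send.{rule}",
          sign="inhibitory" if rule in ("1a", "1b") else "excitatory",
          kind="highpass" if rule in ("2i", "2c") else "basic")
    recv_exc = u("coord.recv.exc", sign="excitatory")
    recv_inh = u("coord.recv.inh", sign="inhibitory")
    syn += [SynapseSpec(recv_exc, sw, 1.0),
            SynapseSpec(recv_inh, sw, 1.0)]
    for joint in ("alpha", "beta"):
        u(f"coord.send.r5.{joint}", sign="excitatory")
        r5e = u(f"coord.recv.r5exc.{joint}", sign="excitatory")
        r5i = u(f"coord.recv.r5inh.{joint}", sign="inhibitory")
        a_name, b_name = BRANCHES[joint]
        syn += [SynapseSpec(r5e, f"{L}.{joint}.{a_name}.pmn", 1.0),
                SynapseSpec(r5i, f"{L}.{joint}.{b_name}.pmn", 1.0)]

    net = NetworkSpec(units=units, synapses=syn)
    ctrl = LegController(leg_id, p)
    return net, ctrl


def unit_census(net: NetworkSpec) -> Dict[str, int]:
    """Count units by structural group (for documentation/tests)."""
    groups: Dict[str, int] = {}
    for unit in net.units:
        group = unit.id.split(".", 2)[1]
        groups[group] = groups.get(group, 0) + 1
    groups["total"] = len(net.units)
    return groups
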