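"""Interleg coordination rules.

Local influences between directly neighboring legs; no global gait clock
exists anywhere.  Implemented channels:

* rule 1 (ipsilateral, rear -> front): inhibits swing start in the
  anterior leg; 1a while the sender swings, 1b an integrator that
  prolongs the inhibition past swing end until the sender's rule-2i pulse
  suppresses it;
* rule 2i (ipsilateral, rear -> front): a velocity-gated charger feeding
  a second-order high-pass produces a phasic swing-triggering pulse
  shortly after the sender's swing ends, later and weaker at low
  velocity;
* rule 3i (ipsilateral, front -> rear): tonic swing excitation while the
  sender's position lies inside a window whose onset threshold shifts
  linearly with velocity;
* rules 2c / 3c (contralateral, symmetric): position-dependent swing
  excitation, 2c through a high-pass (fades at low velocity), 3c tonic;
* rule 5 (5i/5c, premotor level): when the sender's retractor (or
  depressor) premotor output is strongly active, it excites the same
  premotor unit of the receiver and inhibits the antagonist - silent
  during undisturbed walking; ipsilateral gain 0.2, contralateral 0.1;
  a treadmill sender multiplies its gain up to 15-fold during the first
  half of stance (alpha sensor > 25 mV);
* rule 5ch: the hind-leg pair carries the sign-inverted version,
  supporting anti-phase coupling.

Backward walking uses only rules 1, 2i and a 2c with a mirrored position
threshold; 3i/3c are deactivated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .leg_controller import CoordIn, LegController
from .neuron_core import BasicUnit, HighpassUnit, IntegratorUnit
from .params import ControllerParams, RuleParams, default_params

IPSI_REAR_TO_FRONT = [("HL", "ML"), ("ML", "FL"), ("HR", "MR"), ("MR", "FR")]
IPSI_FRONT_TO_REAR = [(b, a) for a, b in IPSI_REAR_TO_FRONT]
CONTRA_PAIRS = [("FL", "FR"), ("ML", "MR"), ("HL", "HR")]
RULE5_JOINTS = ("alpha", "beta")
# rule-5 coupled branches and their antagonists per joint
_R5_MAIN = {"alpha": ("ret", "pro"), "beta": ("dep", "lev")}


@dataclass
class RuleChannel:
    """One directed rule channel between neighboring legs."""

    rule: str
    sender: str
    receiver: str
    gain: float = 1.0
    # filter states (allocated on demand per rule)
    integrator: Optional[IntegratorUnit] = None
    charger: Optional[BasicUnit] = None
    hpf1: Optional[HighpassUnit] = None
    hpf2: Optional[HighpassUnit] = None
    last_output: float = 0.0
    last_aux: float = 0.0  # rule 1: 2i-activity used to gate 1b


def _oriented_p(leg: LegController, alpha: float) -> float:
    return leg.oriented_p(alpha)


def rule1_step(ch: RuleChannel, sender: LegController,
               sender_swinging: bool, rule2i_active: float,
               rp: RuleParams) -> float:
    """Inhibition of the receiver's swing start (sections 1a + 1b)."""
    out_1a = rp.w_1a if sender_swinging else 0.0
    assert ch.integrator is not None
    drive = 30.0 if sender_swinging else 0.0
    gate = max(0.0, 1.0 - rule2i_active / rp.gate_1b)  # 2i suppresses 1b
    out_1b = rp.w_1b / 30.0 * ch.integrator.step(drive) * gate
    ch.last_output = out_1a + out_1b
    return ch.last_output


def rule2i_step(ch: RuleChannel, sender_in_stance: bool, velocity: float,
                rp: RuleParams) -> float:
    """Phasic swing excitation shortly after the sender's swing end.

    While the sender swings, the charger is held at zero (disinhibition
    happens at swing end).  In stance it charges toward the velocity
    value with a slow membrane constant; the cascaded high-pass stages
    convert the rise into a pulse whose latency shrinks and amplitude
    grows with velocity.
    """
    assert ch.charger and ch.hpf1 and ch.hpf2
    # saturating velocity drive: the pulse grows quickly from zero at very
    # low velocities but levels off toward the fast range
    drive = (50.0 * velocity / (velocity + rp.sat_2i)
             if sender_in_stance else 0.0)
    c = ch.charger.step(drive)
    h1 = ch.hpf1.step(c)
    h2 = ch.hpf2.step(h1)
    ch.last_output = rp.w_2i * h2
    return ch.last_output


def rule2c_step(ch: RuleChannel, sender_p: float, sender_in_stance: bool,
                rp: RuleParams, thr: Optional[float] = None) -> float:
    """Contralateral phasic excitation from the sender's position.

    The analog gate signal rises as the sender retracts past the
    threshold; the high-pass transmits its rate of change, so the effect
    shrinks with decreasing velocity.
    """
    assert ch.hpf1 is not None
    thr = rp.thr_2c if thr is None else thr
    sig = max(0.0, (thr - sender_p) * rp.slope_2c) if sender_in_stance else 0.0
    ch.last_output = rp.w_2c * ch.hpf1.step(min(sig, 50.0))
    return ch.last_output


def rule3_step(ch: RuleChannel, sender_p: float, sender_in_stance: bool,
               velocity: float, rp: RuleParams) -> float:
    """Tonic window excitation (3i front->rear; 3c contralateral)."""
    if ch.rule == "3i":
        on = rp.thr3i_on + rp.thr3i_vel_slope * (velocity - 25.0)
        off = rp.thr3i_off
        w = rp.w_3i
    else:
        on = rp.thr3c_on + rp.thr3c_vel_slope * (velocity - 25.0)
        off = rp.thr3c_off
        w = rp.w_3c
    active = sender_in_stance and off <= sender_p <= on
    ch.last_output = w if active else 0.0
    return ch.last_output


def rule5_send(sender_pmn: float, rp: RuleParams,
               treadmill_mode: bool = False,
               sender_alpha_sensor: float = 0.0) -> float:
    """Activation of the sender's "output 5" unit.

    The unit responds only to strong premotor activation (so it is silent
    during undisturbed walking) and saturates at 50 mV.  A treadmill
    sender multiplies its premotor signal by the friction factor (up to
    15) while the alpha sensor indicates the first half of stance.
    """
    sig = sender_pmn
    cap = 50.0
    if treadmill_mode and sender_alpha_sensor > rp.treadmill_alpha_thr:
        # the friction factor scales the whole transmitted influence
        sig *= rp.treadmill_boost
        cap *= rp.treadmill_boost
    excess = sig - rp.thr_5
    if excess <= 0.0:
        return 0.0
    return min(cap, rp.k_send * excess)


def rule5_step(ch: RuleChannel, sender_out5: float, rp: RuleParams,
               treadmill_mode: bool = False,
               sender_alpha_sensor: float = 0.0) -> Tuple[float, float]:
    """(excitation to the coupled PMN, inhibition to its antagonist).

    ``sender_out5`` is the sender's "output 5" activation for the joint;
    when the raw premotor output is passed instead, the send stage is
    applied first (kept for convenience in isolated-channel use).
    """
    val = ch.gain * sender_out5
    ch.last_output = val
    return val, val


def rule5ch_step(ch: RuleChannel, sender_out5: float,
                 rp: RuleParams) -> Tuple[float, float]:
    """Hind-leg anti-phase channel: sign-inverted rule 5.

    Returns (excitation to the *antagonist* PMN, inhibition to the
    coupled PMN) of the receiving leg.
    """
    return rule5_step(ch, sender_out5, rp)


@dataclass
class CoordinationTopology:
    """All rule channels for one walking mode."""

    mode: str = "forward"
    channels: List[RuleChannel] = field(default_factory=list)
    params: ControllerParams = field(default_factory=default_params)

    def edge_list(self) -> List[Tuple[str, str, str, float]]:
        return [(c.sender, c.receiver, c.rule, c.gain) for c in self.channels]

    def to_csv(self) -> str:
        lines = ["sender,receiver,rule,gain"]
        lines += [f"{s},{r},{rule},{g}" for s, r, rule, g in self.edge_list()]
        return "\n".join(lines) + "\n"


def build_topology(mode: str = "forward",
                   params: Optional[ControllerParams] = None
                   ) -> CoordinationTopology:
    """Assemble the channel set for forward or backward walking."""
    if mode not in ("forward", "backward"):
        raise ValueError(f"unknown mode {mode!r}")
    p = params or default_params()
    rp = p.rules
    chans: List[RuleChannel] = []

    def mk_rule1(s: str, r: str) -> RuleChannel:
        return RuleChannel(
            rule="1", sender=s, receiver=r,
            integrator=IntegratorUnit(Cm=rp.tau_1b_cm, w_self=rp.w_1b_self),
        )

    def mk_rule2i(s: str, r: str) -> RuleChannel:
        return RuleChannel(
            rule="2i", sender=s, receiver=r,
            charger=BasicUnit(Cm=rp.cm_2i_charge),
            hpf1=HighpassUnit(tau_fall=rp.tau_2i_hpf),
            hpf2=HighpassUnit(tau_fall=rp.tau_2i_hpf),
        )

    for s, r in IPSI_REAR_TO_FRONT:
        chans.append(mk_rule1(s, r))
        chans.append(mk_rule2i(s, r))
    for a, b in CONTRA_PAIRS:
        for s, r in ((a, b), (b, a)):
            chans.append(RuleChannel(rule="2c", sender=s, receiver=r,
                                     hpf1=HighpassUnit(tau_fall=rp.tau_2c)))
    if mode == "forward":
        for s, r in IPSI_FRONT_TO_REAR:
            chans.append(RuleChannel(rule="3i", sender=s, receiver=r))
        for a, b in CONTRA_PAIRS:
            for s, r in ((a, b), (b, a)):
                chans.append(RuleChannel(rule="3c", sender=s, receiver=r))
        # rule 5: every neighbor pair in both directions, except hind-hind
        for a, b in IPSI_REAR_TO_FRONT:
            for s, r in ((a, b), (b, a)):
                chans.append(RuleChannel(rule="5i", sender=s, receiver=r,
                                         gain=rp.gain_5_ipsi))
        for a, b in CONTRA_PAIRS[:2]:
            for s, r in ((a, b), (b, a)):
                chans.append(RuleChannel(rule="5c", sender=s, receiver=r,
                                         gain=rp.gain_5_contra))
        for s, r in (("HL", "HR"), ("HR", "HL")):
            chans.append(RuleChannel(rule="5ch", sender=s, receiver=r,
                                     gain=rp.gain_5_contra))
    return CoordinationTopology(mode=mode, channels=chans, params=p)


_IPSI_NEIGHBORS: Dict[str, Tuple[str, ...]] = {
    "FL": ("ML",), "ML": ("FL", "HL"), "HL": ("ML",),
    "FR": ("MR",), "MR": ("FR", "HR"), "HR": ("MR",),
}
_CONTRA_NEIGHBOR: Dict[str, str] = {
    "FL": "FR", "FR": "FL", "ML": "MR", "MR": "ML", "HL": "HR", "HR": "HL",
}


class CoordinationEngine:
    """Steps every channel each neural tick and aggregates receiver input."""

    def __init__(self, topology: CoordinationTopology) -> None:
        self.topo = topology
        self.rp = topology.params.rules
        # cache the 2i channel per (sender) to gate the sender's rule 1b
        self._r2i_by_sender: Dict[str, RuleChannel] = {
            c.sender: c for c in topology.channels if c.rule == "2i"
        }
        # rule-5 "output 5" activations per leg and joint (previous tick);
        # out5_raw is the unadapted send signal used by the tonic 5ch link
        self.out5: Dict[str, Dict[str, float]] = {
            lid: {j: 0.0 for j in RULE5_JOINTS}
            for lid in _IPSI_NEIGHBORS
        }
        self.out5_raw: Dict[str, Dict[str, float]] = {
            lid: {j: 0.0 for j in RULE5_JOINTS}
            for lid in _IPSI_NEIGHBORS
        }
        # transmitted value per channel source: treadmill senders bypass
        # the send-unit saturation and adaptation (their boosted signal is
        # already phasic, gated by the first half of stance)
        self.out5_tx: Dict[str, Dict[str, float]] = {
            lid: {j: 0.0 for j in RULE5_JOINTS}
            for lid in _IPSI_NEIGHBORS
        }
        # phasic dynamics of the send units: the coupling acts at burst
        # onsets but cannot sustain a static (latched) network state
        self._send_hpf: Dict[str, Dict[str, HighpassUnit]] = {
            lid: {
                j: HighpassUnit(tau_fall=self.rp.tau_5_send)
                for j in RULE5_JOINTS
            }
            for lid in _IPSI_NEIGHBORS
        }

    def _update_out5(self, legs: Dict[str, LegController],
                     sensors: Dict[str, "object"],
                     treadmill_legs: set) -> None:
        """Send/relay layer of rule 5.

        Each leg's "output 5" unit carries its own thresholded premotor
        signal or, failing that, a relayed copy of a neighbor's unit
        (attenuated, saturating selection), so a pilocarpine rhythm
        propagates along a chain of untreated hemiganglia.  The hind-hind
        channel (5ch) does not take part in the relay.
        """
        rp = self.rp
        prev = self.out5
        new: Dict[str, Dict[str, float]] = {}
        new_raw: Dict[str, Dict[str, float]] = {}
        for lid, leg in legs.items():
            sf = sensors[lid]
            tm = lid in treadmill_legs
            new[lid] = {}
            new_raw[lid] = {}
            for joint in RULE5_JOINTS:
                main, _ = _R5_MAIN[joint]
                # the send unit carries a stance/load signal: premotor
                # activity of a swinging leg (e.g. the depressor pulling
                # the leg down) is not broadcast
                if leg.mode == "stance":
                    raw = rule5_send(
                        leg.pmn_out[(joint, main)], rp,
                        treadmill_mode=tm, sender_alpha_sensor=sf.alpha,
                    )
                else:
                    raw = 0.0
                intrinsic = self._send_hpf[lid][joint].step(min(raw, 50.0))
                self.out5_tx[lid][joint] = raw if tm else intrinsic
                relay = 0.0
                for nbr in _IPSI_NEIGHBORS[lid]:
                    relay = max(relay, rp.relay_ipsi * prev[nbr][joint])
                contra = _CONTRA_NEIGHBOR[lid]
                if not (lid.startswith("H") and contra.startswith("H")):
                    relay = max(relay,
                                rp.relay_contra * prev[contra][joint])
                new[lid][joint] = min(50.0, max(intrinsic, relay))
                new_raw[lid][joint] = min(raw, 50.0)
        self.out5 = new
        self.out5_raw = new_raw

    def step(self, legs: Dict[str, LegController],
             sensors: Dict[str, "object"],
             treadmill_legs: Optional[set] = None) -> Dict[str, CoordIn]:
        """One 1 ms coordination sweep. ``sensors`` maps leg -> SensorFrame."""
        treadmill_legs = treadmill_legs or set()
        rp = self.rp
        out: Dict[str, CoordIn] = {lid: CoordIn() for lid in legs}
        for ch in self.topo.channels:
            sl = legs[ch.sender]
            sf = sensors[ch.sender]
            rx = out[ch.receiver]
            swinging = sl.mode == "swing"
            in_stance = not swinging
            p = sl.oriented_p(sf.alpha)
            vel = sl.vel_local
            if sl.deafferented and ch.rule in ("1", "2i", "2c", "3i", "3c"):
                # rules 1-3 are position/state driven; a deafferented leg
                # has no afference to feed them
                continue
            if ch.rule == "1":
                r2i = self._r2i_by_sender.get(ch.sender)
                r2i_act = r2i.last_output if r2i else 0.0
                rx.swing_inh += rule1_step(ch, sl, swinging, r2i_act, rp)
            elif ch.rule == "2i":
                rx.swing_exc += rule2i_step(ch, in_stance, vel, rp)
            elif ch.rule == "2c":
                thr = (rp.backward_2c_thr
                       if self.topo.mode == "backward" else None)
                rx.swing_exc += rule2c_step(ch, p, in_stance, rp, thr=thr)
            elif ch.rule in ("3i", "3c"):
                rx.swing_exc += rule3_step(ch, p, in_stance, vel, rp)
            elif ch.rule in ("5i", "5c", "5ch"):
                for joint in RULE5_JOINTS:
                    main, antag = _R5_MAIN[joint]
                    src = (self.out5_tx if ch.sender in treadmill_legs
                           else self.out5)
                    val, _ = rule5_step(ch, src[ch.sender][joint], rp)
                    if val <= 0.0:
                        continue
                    if ch.rule == "5ch":
                        # inverted: inhibit retractor side, excite antagonist
                        rx.pmn_add[(joint, main)] = (
                            rx.pmn_add.get((joint, main), 0.0) - val)
                        rx.pmn_add[(joint, antag)] = (
                            rx.pmn_add.get((joint, antag), 0.0) + val)
                    else:
                        rx.pmn_add[(joint, main)] = (
                            rx.pmn_add.get((joint, main), 0.0) + val)
                        rx.pmn_add[(joint, antag)] = (
                            rx.pmn_add.get((joint, antag), 0.0) - val)
        self._update_out5(legs, sensors, treadmill_legs)
        return out
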