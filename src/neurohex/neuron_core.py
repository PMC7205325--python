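"""Discrete-time leaky rate-neuron engine.

All controllers in this package are built from one neuron model: a leaky
integrator updated at 1 ms,

    v' = v + (-v + I_syn + I_app) / Cm

with a piecewise-linear output characteristic clipped to [0, 50] mV.
Synaptic input is summed separately for excitatory and inhibitory
afferents, each sum clipped at 80 mV.  Every unit is either excitatory or
inhibitory (Dale's law); synaptic weights are therefore non-negative and
the sign is carried by the presynaptic unit.  Selected units additionally
carry a phasic (band-pass) characteristic, realized as a nonlinear
high-pass filter with a slow decay constant (default 10 s) and a fast
recovery constant (0.01 s) for internal values below 0 mV.

Two layers of API are provided:

* a declarative network description (:class:`UnitSpec`, :class:`SynapseSpec`,
  :class:`NetworkSpec`) with a synchronous interpreter (:func:`step_network`)
  and structural checks (:func:`check_dale`), serializable to YAML/CSV;
* lightweight scalar state classes (:class:`BasicUnit`, :class:`HighpassUnit`,
  :class:`IntegratorUnit`) with the same update semantics, used by the leg
  controllers where the wiring is fixed and speed matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import yaml

DT_NEURAL_MS = 1.0
DT_NEURAL_S = 1e-3
V_MAX = 50.0
I_CLIP = 80.0
CM_DEFAULT = 4.5
TAU_FALL_DEFAULT = 10.0
TAU_RISE_DEFAULT = 0.01

EXC = "excitatory"
INH = "inhibitory"


def clip_output(v: float) -> float:
    """Piecewise-linear activation: clip membrane voltage to [0, 50] mV."""
    if v < 0.0:
        return 0.0
    if v > V_MAX:
        return V_MAX
    return v


# ---------------------------------------------------------------------------
# declarative network description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSpec:
    """Static description of one rate neuron.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a network.
    kind : {"basic", "highpass"}
    sign : {"excitatory", "inhibitory"}
        Sign of all outgoing synapses (Dale's law).
    Cm : float
        Membrane constant in update-step units (dimensionless multiples of
        the 1 ms tick); default 4.5.
    tau_fall, tau_rise : float
        High-pass constants in seconds (highpass units only).
    """

    id: str
    kind: str = "basic"
    sign: str = EXC
    Cm: float = CM_DEFAULT
    tau_fall: float = TAU_FALL_DEFAULT
    tau_rise: float = TAU_RISE_DEFAULT

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError(f"unit {self.id}: Cm must be > 0")
        if self.kind not in ("basic", "highpass"):
            raise ValueError(f"unit {self.id}: unknown kind {self.kind!r}")
        if self.sign not in (EXC, INH):
            raise ValueError(f"unit {self.id}: unknown sign {self.sign!r}")
        if self.kind == "highpass" and not (self.tau_fall > self.tau_rise > 0):
            raise ValueError(
                f"unit {self.id}: require tau_fall > tau_rise > 0"
            )


@dataclass
class UnitState:
    """Dynamic state of one unit: membrane voltage and clipped output."""

    v: float = 0.0
    output: float = 0.0
    baseline: float = 0.0  # highpass units: slow tracker of the input

    def refresh(self) -> None:
        self.output = clip_output(self.v)


@dataclass(frozen=True)
class SynapseSpec:
    """Connection pre -> post with non-negative weight.

    ``modulation="presynaptic_inhibition"`` marks a synapse whose
    contribution is scaled multiplicatively by ``(1 - gate/50)`` where
    ``gate`` is the output of ``gate_unit`` (divisive normalization).
    """

    pre: str
    post: str
    weight: float
    modulation: str = "none"
    gate_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(
                f"synapse {self.pre}->{self.post}: weight must be >= 0"
            )
        if self.modulation == "presynaptic_inhibition" and not self.gate_unit:
            raise ValueError(
                f"synapse {self.pre}->{self.post}: presynaptic inhibition "
                "requires a gate unit"
            )


@dataclass
class NetworkSpec:
    """Collection of units and synapses updated synchronously at 1 ms."""

    units: List[UnitSpec] = field(default_factory=list)
    synapses: List[SynapseSpec] = field(default_factory=list)
    external_inputs: Dict[str, str] = field(default_factory=dict)
    dt_neural: float = DT_NEURAL_MS

    def __post_init__(self) -> None:
        ids = {u.id for u in self.units}
        if len(ids) != len(self.units):
            raise ValueError("duplicate unit ids")
        for s in self.synapses:
            if s.pre not in ids or s.post not in ids:
                raise ValueError(f"synapse {s.pre}->{s.post}: unknown unit")
            if s.gate_unit is not None and s.gate_unit not in ids:
                raise ValueError(f"synapse {s.pre}->{s.post}: unknown gate")

    def unit(self, uid: str) -> UnitSpec:
        for u in self.units:
            if u.id == uid:
                return u
        raise KeyError(uid)

    def initial_states(self) -> Dict[str, UnitState]:
        return {u.id: UnitState() for u in self.units}

    # -- serialization ----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "dt_neural_ms": self.dt_neural,
            "units": [
                {
                    "id": u.id,
                    "kind": u.kind,
                    "sign": u.sign,
                    "Cm": u.Cm,
                    **(
                        {"tau_fall": u.tau_fall, "tau_rise": u.tau_rise}
                        if u.kind == "highpass"
                        else {}
                    ),
                }
                for u in self.units
            ],
            "synapses": [
                {
                    "pre": s.pre,
                    "post": s.post,
                    "weight": s.weight,
                    **(
                        {"modulation": s.modulation, "gate": s.gate_unit}
                        if s.modulation != "none"
                        else {}
                    ),
                }
                for s in self.synapses
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        units = [
            UnitSpec(
                id=u["id"],
                kind=u.get("kind", "basic"),
                sign=u.get("sign", EXC),
                Cm=u.get("Cm", CM_DEFAULT),
                tau_fall=u.get("tau_fall", TAU_FALL_DEFAULT),
                tau_rise=u.get("tau_rise", TAU_RISE_DEFAULT),
            )
            for u in doc["units"]
        ]
        syns = [
            SynapseSpec(
                pre=s["pre"],
                post=s["post"],
                weight=s["weight"],
                modulation=s.get("modulation", "none"),
                gate_unit=s.get("gate"),
            )
            for s in doc.get("synapses", [])
        ]
        return cls(units=units, synapses=syns,
                   dt_neural=doc.get("dt_neural_ms", DT_NEURAL_MS))

    def to_tables(self):
        """Unit and synapse tables as pandas DataFrames (for CSV export)."""
        import pandas as pd

        units = pd.DataFrame(
            [
                {"id": u.id, "kind": u.kind, "sign": u.sign, "Cm": u.Cm}
                for u in self.units
            ]
        )
        syns = pd.DataFrame(
            [
                {
                    "pre": s.pre,
                    "post": s.post,
                    "weight": s.weight,
                    "modulation": s.modulation,
                }
                for s in self.synapses
            ]
        )
        return units, syns


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def step_unit(state: UnitState, I_syn: float, I_app: float,
              spec: UnitSpec) -> UnitState:
    """One 1 ms update of a basic unit: v' = v + (-v + Isyn + Iapp)/Cm."""
    if spec.kind != "basic":
        raise ValueError("step_unit applies to basic units only")
    if not (math.isfinite(I_syn) and math.isfinite(I_app)
            and math.isfinite(state.v)):
        raise FloatingPointError("non-finite input to step_unit")
    v = state.v + (-state.v + I_syn + I_app) / spec.Cm
    out = UnitState(v=v)
    out.refresh()
    return out


def aggregate_synaptic_input(
    incoming: Iterable[Tuple[float, float, str]],
    presyn_gates: Optional[Iterable[Optional[float]]] = None,
) -> Tuple[float, float]:
    """Sum weighted presynaptic outputs separately by sign, clip at 80 mV.

    ``incoming`` yields ``(presynaptic output mV, weight, sign)`` triples.
    ``presyn_gates`` optionally yields a gate output (mV) per triple; a gate
    scales its synapse's contribution by ``(1 - gate/50)`` before summation
    (presynaptic inhibition / divisive normalization).

    Returns ``(I_exc, I_inh)``; the net drive is ``I_exc - I_inh``.
    """
    items = list(incoming)
    gates: List[Optional[float]] = (
        list(presyn_gates) if presyn_gates is not None else [None] * len(items)
    )
    e = 0.0
    i = 0.0
    for (out, w, sign), gate in zip(items, gates):
        if w < 0:
            raise ValueError("negative synaptic weight")
        contrib = w * out
        if gate is not None:
            contrib *= max(0.0, 1.0 - clip_output(gate) / V_MAX)
        if sign == EXC:
            e += contrib
        else:
            i += contrib
    return min(e, I_CLIP), min(i, I_CLIP)


def step_highpass_unit(state: UnitState, inp: float, spec: UnitSpec,
                       dt: float = DT_NEURAL_S) -> UnitState:
    """One update of a phasic (band-pass) unit.

    The unit transmits ``clip(input - baseline)`` where ``baseline`` is a
    leaky tracker of the input: it follows with the slow constant
    ``tau_fall`` while the difference is positive (so a maintained step
    decays away over ~``tau_fall``) and with the fast constant ``tau_rise``
    while the internal difference is negative (rapid recovery after the
    input drops), matching the asymmetric time constants of the model.
    """
    if spec.kind != "highpass":
        raise ValueError("step_highpass_unit applies to highpass units only")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    diff = inp - state.baseline
    tau = spec.tau_fall if diff > 0 else spec.tau_rise
    baseline = state.baseline + diff * (dt / tau)
    v = inp - baseline
    out = UnitState(v=v, baseline=baseline)
    out.refresh()
    return out


def step_network(
    net: NetworkSpec,
    states: Mapping[str, UnitState],
    external: Optional[Mapping[str, float]] = None,
) -> Dict[str, UnitState]:
    """One synchronous 1 ms sweep over the network.

    All synaptic inputs are computed from the previous step's outputs, then
    every unit is stepped once.  Deterministic given identical inputs.
    """
    external = external or {}
    for u in net.units:
        if u.id not in states:
            raise KeyError(f"missing state for unit {u.id}")
    incoming: Dict[str, List[Tuple[float, float, str]]] = {
        u.id: [] for u in net.units
    }
    gates: Dict[str, List[Optional[float]]] = {u.id: [] for u in net.units}
    sign_of = {u.id: u.sign for u in net.units}
    for s in net.synapses:
        incoming[s.post].append(
            (states[s.pre].output, s.weight, sign_of[s.pre])
        )
        gates[s.post].append(
            states[s.gate_unit].output if s.gate_unit else None
        )
    new: Dict[str, UnitState] = {}
    for u in net.units:
        e, i = aggregate_synaptic_input(incoming[u.id], gates[u.id])
        i_syn = e - i
        i_app = float(external.get(u.id, 0.0))
        if u.kind == "basic":
            new[u.id] = step_unit(states[u.id], i_syn, i_app, u)
        else:
            new[u.id] = step_highpass_unit(
                states[u.id], i_syn + i_app, u, DT_NEURAL_S
            )
    return new


def check_dale(net: NetworkSpec) -> List[str]:
    """Return ids of units violating Dale's law.

    With the sign carried on the unit itself a violation can only be
    introduced by bypassing the constructors, but shipped networks are
    checked for consistency: a unit listed with both signs across duplicate
    declarations, or a synapse table annotated with per-synapse signs that
    contradict the unit sign, would be caught here.  The check inspects the
    effective sign of every outgoing synapse.
    """
    sign_of = {u.id: u.sign for u in net.units}
    seen: Dict[str, set] = {}
    for s in net.synapses:
        seen.setdefault(s.pre, set()).add(sign_of[s.pre])
    return sorted(uid for uid, signs in seen.items() if len(signs) > 1)


# ---------------------------------------------------------------------------
# scalar unit classes (fast path used inside the leg controllers)
# ---------------------------------------------------------------------------

class BasicUnit:
    """Scalar leaky-integrator unit, same semantics as :func:`step_unit`."""

    __slots__ = ("v", "output", "inv_cm")

    def __init__(self, Cm: float = CM_DEFAULT, v0: float = 0.0) -> None:
        self.inv_cm = 1.0 / Cm
        self.v = v0
        self.output = clip_output(v0)

    def step(self, i_total: float) -> float:
        v = self.v + (-self.v + i_total) * self.inv_cm
        self.v = v
        self.output = 0.0 if v < 0.0 else (V_MAX if v > V_MAX else v)
        return self.output


class HighpassUnit:
    """Scalar phasic unit, same semantics as :func:`step_highpass_unit`."""

    __slots__ = ("baseline", "output", "k_fall", "k_rise")

    def __init__(self, tau_fall: float = TAU_FALL_DEFAULT,
                 tau_rise: float = TAU_RISE_DEFAULT,
                 dt: float = DT_NEURAL_S) -> None:
        if not tau_fall > tau_rise > 0:
            raise ValueError("require tau_fall > tau_rise > 0")
        self.k_fall = dt / tau_fall
        self.k_rise = dt / tau_rise
        self.baseline = 0.0
        self.output = 0.0

    def step(self, inp: float) -> float:
        diff = inp - self.baseline
        self.baseline += diff * (self.k_fall if diff > 0 else self.k_rise)
        v = inp - self.baseline
        self.output = 0.0 if v < 0.0 else (V_MAX if v > V_MAX else v)
        return self.output


class IntegratorUnit:
    """Leaky unit with recurrent self-excitation (slow integrator).

    Used by coordination rule 1b: self-weight just below 1 stretches the
    effective time constant so inhibition outlasts the driving signal.
    """

    __slots__ = ("v", "output", "inv_cm", "w_self")

    def __init__(self, Cm: float = CM_DEFAULT, w_self: float = 0.9) -> None:
        self.inv_cm = 1.0 / Cm
        self.w_self = w_self
        self.v = 0.0
        self.output = 0.0

    def step(self, i_ext: float) -> float:
        i_total = i_ext + self.w_self * self.output
        v = self.v + (-self.v + i_total) * self.inv_cm
        self.v = v
        self.output = 0.0 if v < 0.0 else (V_MAX if v > V_MAX else v)
        return self.output
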