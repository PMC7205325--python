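"""Spatially-coded ring network for stance direction control.

Each leg carries a five-layer network of 12 units per layer that converts
the desired walking direction (angle theta, given as an integer spatial
code) and the current alpha-joint position into velocity contributions for
the alpha joint (retractor, output O2) and the gamma joint (flexor O3 /
extensor O4).  Twelve units span 180 degrees, so one unit codes a 15-degree
sector.  The input stage computes

    alpha* = (alpha + 50) / 3          (alpha sensor in mV)
    delta  = alpha* - theta            (in spatial-code units)

and activates layer-1 units 1..delta cumulatively; layer 2 selects the
topmost active unit (the winner), layer 3 is its complement and disinhibits
layers 4/5 only at the winner index.  Layers 4 and 5 scale the leg-local
stance velocity by 0.2*sin and 0.2*cos of the winner's sector angle: the
output pair approximates a velocity vector of magnitude 0.2*vel pointing in
the desired direction, quantized to 15 degrees.

The protractor output O1 exists in the data model but is fixed at 0 in
this version (it would only be needed for very tight turns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

N_UNITS = 12
SECTOR_DEG = 15.0
BIN_WIDTH_MV = 50.0 / N_UNITS  # code-space bin width
GAIN = 0.2
GAMMA_STANCE_LIMIT_MV = 35.0


@dataclass
class RingNetInput:
    alpha_sensor: float  # protractor-branch position sensor, mV in [0, 50]
    theta_code: int = 0  # integer spatial-code offset; 0 = straight forward
    vel: float = 0.0     # leg-local stance velocity, mV >= 0


@dataclass
class RingNetState:
    layer1: List[int] = field(default_factory=lambda: [0] * N_UNITS)
    layer2: List[int] = field(default_factory=lambda: [0] * N_UNITS)
    layer3: List[int] = field(default_factory=lambda: [0] * N_UNITS)
    layer4: List[float] = field(default_factory=lambda: [0.0] * N_UNITS)
    layer5: List[float] = field(default_factory=lambda: [0.0] * N_UNITS)
    winner: Optional[int] = None  # 1..12


@dataclass
class RingNetOutput:
    O1: float = 0.0  # protractor (unused, fixed 0)
    O2: float = 0.0  # retractor velocity, mV
    O3: float = 0.0  # flexor velocity, mV
    O4: float = 0.0  # extensor velocity, mV


def encode_delta(alpha_sensor: float, theta_code: int = 0) -> int:
    """Map the alpha sensor and direction code to a spatial code 1..12.

    alpha* = (alpha + 50)/3; the alpha code is the smallest k with
    alpha* <= k * (50/12), boundary values resolving to the lower code;
    theta is subtracted in code space and the result floored at 1.
    """
    if not 0.0 <= alpha_sensor <= 50.0:
        raise ValueError(f"alpha sensor out of range: {alpha_sensor}")
    alpha_star = (alpha_sensor + 50.0) / 3.0
    # smallest k with alpha* <= k*BIN_WIDTH_MV; exact boundaries go down
    k = math.ceil(alpha_star / BIN_WIDTH_MV - 1e-9)
    k = max(1, min(N_UNITS, k))
    code = k - int(theta_code)
    return max(1, min(N_UNITS, code))


def layer_stack_step(code: int) -> RingNetState:
    """Activate the binary layers 1-3 for a given spatial code."""
    if not 1 <= code <= N_UNITS:
        raise ValueError(f"code out of range: {code}")
    st = RingNetState()
    for j in range(code):
        st.layer1[j] = 1
    st.layer2[code - 1] = 1
    st.layer3 = [1 - x for x in st.layer2]
    st.winner = code
    return st


def sector_angle_deg(winner: int) -> float:
    """Center angle of the winner's 15-degree sector."""
    return (winner - 0.5) * SECTOR_DEG


def compute_outputs(state: RingNetState, vel: float) -> RingNetOutput:
    """Velocity decomposition at the winner sector.

    O2 (retractor) = vel * 0.2 * sin(phi); the gamma component
    vel * 0.2 * cos(phi) is routed to the extensor O4 for sectors 1..6 and
    to the flexor O3 for sectors 7..12 (magnitude of cos).
    """
    if state.winner is None:
        raise ValueError("ring net has no winner")
    if vel < 0:
        raise ValueError("vel must be >= 0")
    phi = math.radians(sector_angle_deg(state.winner))
    out = RingNetOutput()
    alpha_drive = vel * GAIN * math.sin(phi)
    gamma_drive = vel * GAIN * abs(math.cos(phi))
    state.layer4 = [0.0] * N_UNITS
    state.layer5 = [0.0] * N_UNITS
    j = state.winner - 1
    state.layer4[j] = alpha_drive
    state.layer5[j] = gamma_drive
    out.O2 = alpha_drive
    if state.winner <= N_UNITS // 2:
        out.O4 = gamma_drive
    else:
        out.O3 = gamma_drive
    return out


def evaluate(alpha_sensor: float, theta_code: int, vel: float) -> RingNetOutput:
    """Full ring-net pass: encode, select winner, decompose velocity."""
    if vel <= 0.0:
        return RingNetOutput()
    code = encode_delta(alpha_sensor, theta_code)
    state = layer_stack_step(code)
    return compute_outputs(state, vel)


@dataclass
class MotorDrives:
    """Premotor drives produced by routing ring-net outputs (all >= 0 mV)."""

    protractor: float = 0.0
    retractor: float = 0.0
    flexor: float = 0.0
    extensor: float = 0.0


def route_to_joints(out: RingNetOutput, leg_state: str, direction: str,
                    gamma_sensor: float = 0.0) -> MotorDrives:
    """Direct ring-net outputs to premotor units.

    Only stance uses the ring net (swing is position-controlled).  In
    forward stance O2 drives the retractor; in backward stance the alpha
    routing is reversed (O2 drives the protractor).  Gamma stance motion
    saturates once the flexion sensor exceeds 35 mV: further flexion drive
    is cut so the leg cannot pull itself under the body during oblique
    (curve) trajectories.
    """
    if leg_state != "stance":
        return MotorDrives()
    d = MotorDrives()
    if direction == "forward":
        d.retractor = out.O2
    elif direction == "backward":
        d.protractor = out.O2
    else:
        raise ValueError(f"unknown direction {direction!r}")
    flex = out.O3
    if gamma_sensor > GAMMA_STANCE_LIMIT_MV:
        flex = 0.0
    d.flexor = flex
    d.extensor = out.O4
    return d


def dump_layers_csv_row(state: RingNetState) -> List[float]:
    """Flatten the five layers into one 60-column row for debug CSV dumps."""
    row: List[float] = []
    row.extend(float(x) for x in state.layer1)
    row.extend(float(x) for x in state.layer2)
    row.extend(float(x) for x in state.layer3)
    row.extend(state.layer4)
    row.extend(state.layer5)
    return row
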