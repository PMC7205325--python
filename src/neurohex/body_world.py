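"""Quasi-static kinematic hexapod body surrogate.

Replaces a rigid-body dynamics simulation with a kinematic consensus
model, justified for slow hexapod walking where inertia effects are
small.  Six identical three-hinge legs (alpha fore-aft, beta up-down,
gamma leg length) hang from a rigid planar body.  Motor neurons command
joint velocities; each motor integrates its command into a desired angle
and carries an elastic element, so the deviation between desired and
actual angle serves as a torque/load proxy (there are no explicit force
sensors).  Body motion is the least-squares consensus of the foot
velocities implied by all contacting, normally-walking stance legs; those
feet are then held fixed in the world and their joint angles
back-computed, so stance feet do not slip.  Interventions support the
neurophysiology protocols: freezing a leg (deafferentation), anchoring an
intact leg to a world-fixed plate (standing on a force transducer), and
treadmill walking (the leg steps but does not propel the body).

Update rate: 10 ms body ticks; the neural controllers run ten 1 ms steps
per body tick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .leg_controller import LEG_IDS, SensorFrame
from .params import ControllerParams, GeometryParams, MotorParams, default_params

DT_BODY = 0.01  # s
NEURAL_PER_BODY = 10

INTERVENTIONS = ("normal", "deafferented_frozen", "fixed_standing",
                 "treadmill")

JOINTS = ("alpha", "beta", "gamma")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class LegGeometry:
    """Mounting point and shared segment lengths for one leg."""

    leg_id: str
    mount: Tuple[float, float]
    side: int  # +1 left, -1 right
    g: GeometryParams

    def angles_deg(self, mv: Dict[str, float]) -> Tuple[float, float, float]:
        gg = self.g
        return (
            gg.alpha_deg_off + gg.alpha_deg_per_mv * mv["alpha"],
            gg.beta_deg_off + gg.beta_deg_per_mv * mv["beta"],
            gg.gamma_deg_off + gg.gamma_deg_per_mv * mv["gamma"],
        )


def make_geometry(params: Optional[ControllerParams] = None
                  ) -> Dict[str, LegGeometry]:
    p = params or default_params()
    g = p.geometry
    mounts = {
        "FL": (g.mount_x_front, g.mount_y_front, 1),
        "FR": (g.mount_x_front, -g.mount_y_front, -1),
        "ML": (g.mount_x_middle, g.mount_y_middle, 1),
        "MR": (g.mount_x_middle, -g.mount_y_middle, -1),
        "HL": (g.mount_x_hind, g.mount_y_hind, 1),
        "HR": (g.mount_x_hind, -g.mount_y_hind, -1),
    }
    return {
        lid: LegGeometry(leg_id=lid, mount=(mx, my), side=side, g=g)
        for lid, (mx, my, side) in mounts.items()
    }


def forward_kinematics(geom: LegGeometry, mv: Dict[str, float],
                       body_height: float) -> Tuple[float, float, float]:
    """Foot position in the body frame (x forward, y left, z up).

    The chain is: alpha rotates the leg plane about the vertical axis at
    the mount; in that plane the femur (at angle beta above horizontal)
    and the tibia (tilted gamma_t from vertical) set the radial distance
    and the drop below the mount.
    """
    for j in JOINTS:
        if not -1e-9 <= mv[j] <= 50.0 + 1e-9:
            raise ValueError(f"{geom.leg_id}: {j} sensor out of range")
    a_deg, b_deg, gt_deg = geom.angles_deg(mv)
    a = math.radians(a_deg)
    b = math.radians(b_deg)
    gt = math.radians(gt_deg)
    gg = geom.g
    u = gg.len_coxa + gg.len_femur * math.cos(b) + gg.len_tibia * math.sin(gt)
    drop = gg.len_tibia * math.cos(gt) - gg.len_femur * math.sin(b)
    fx = geom.mount[0] + u * math.sin(a)
    fy = geom.mount[1] + geom.side * u * math.cos(a)
    fz = body_height - drop
    return fx, fy, fz


def inverse_kinematics(geom: LegGeometry, foot_body: Tuple[float, float, float],
                       body_height: float,
                       beta_prev_mv: float) -> Tuple[Dict[str, float], bool]:
    """Joint sensor values (mV) placing the foot at ``foot_body``.

    Returns ``(mv, reached)``; when the point is outside the workspace the
    nearest reachable posture is returned with ``reached=False`` (the foot
    slips).  Of the two beta solutions the one closer to the previous beta
    is selected.
    """
    gg = geom.g
    dx = foot_body[0] - geom.mount[0]
    dy = (foot_body[1] - geom.mount[1]) * geom.side
    u_h = math.hypot(dx, dy)
    alpha = math.degrees(math.atan2(dx, dy))
    drop = body_height - foot_body[2]
    a = u_h - gg.len_coxa
    lf, lt = gg.len_femur, gg.len_tibia
    C = (a * a + lf * lf + drop * drop - lt * lt) / (2.0 * lf)
    R = math.hypot(a, drop)
    reached = True
    if R < 1e-9:
        return ({"alpha": _deg_to_mv(geom, "alpha", alpha),
                 "beta": beta_prev_mv, "gamma": 25.0}, False)
    ratio = C / R
    if abs(ratio) > 1.0:
        ratio = max(-1.0, min(1.0, ratio))
        reached = False
    phi = math.atan2(drop, a)
    ang = math.acos(ratio)
    beta_prev = math.radians(
        gg.beta_deg_off + gg.beta_deg_per_mv * beta_prev_mv)
    cands = [ang - phi, -ang - phi]
    beta = min(cands, key=lambda b: abs(b - beta_prev))
    gt = math.atan2(a - lf * math.cos(beta), drop + lf * math.sin(beta))
    mv = {
        "alpha": _deg_to_mv(geom, "alpha", alpha),
        "beta": _deg_to_mv(geom, "beta", math.degrees(beta)),
        "gamma": _deg_to_mv(geom, "gamma", math.degrees(gt)),
    }
    clipped = any(not 0.0 <= v <= 50.0 for v in mv.values())
    mv = {k: max(0.0, min(50.0, v)) for k, v in mv.items()}
    return mv, reached and not clipped


def _deg_to_mv(geom: LegGeometry, joint: str, deg: float) -> float:
    gg = geom.g
    off, slope = {
        "alpha": (gg.alpha_deg_off, gg.alpha_deg_per_mv),
        "beta": (gg.beta_deg_off, gg.beta_deg_per_mv),
        "gamma": (gg.gamma_deg_off, gg.gamma_deg_per_mv),
    }[joint]
    return (deg - off) / slope


def _mv_rate_to_body_jacobian(geom: LegGeometry, mv: Dict[str, float],
                              rates_mv: Dict[str, float]
                              ) -> Tuple[float, float, float]:
    """Foot velocity in the body frame implied by sensor-space rates."""
    gg = geom.g
    a_deg, b_deg, gt_deg = geom.angles_deg(mv)
    a, b, gt = (math.radians(x) for x in (a_deg, b_deg, gt_deg))
    da = math.radians(gg.alpha_deg_per_mv) * rates_mv["alpha"]
    db = math.radians(gg.beta_deg_per_mv) * rates_mv["beta"]
    dgt = math.radians(gg.gamma_deg_per_mv) * rates_mv["gamma"]
    u = gg.len_coxa + gg.len_femur * math.cos(b) + gg.len_tibia * math.sin(gt)
    du = -gg.len_femur * math.sin(b) * db + gg.len_tibia * math.cos(gt) * dgt
    ddrop = -gg.len_tibia * math.sin(gt) * dgt - gg.len_femur * math.cos(b) * db
    vx = du * math.sin(a) + u * math.cos(a) * da
    vy = geom.side * (du * math.cos(a) - u * math.sin(a) * da)
    vz = -ddrop  # foot vertical velocity relative to the body
    return vx, vy, vz


# ---------------------------------------------------------------------------
# motors and body state
# ---------------------------------------------------------------------------

@dataclass
class MotorState:
    """One joint's motor: desired angle integrator plus elastic element.

    ``desired`` integrates the commanded velocity (with a slow relaxation
    toward the actual angle so the spring cannot wind up indefinitely);
    ``actual`` is the reached angle, possibly overridden by kinematic
    constraints.  ``torque_proxy = k * (desired - actual)``.
    """

    spring_k: float
    desired: float = 25.0
    actual: float = 25.0

    @property
    def torque_proxy(self) -> float:
        return self.spring_k * (self.desired - self.actual)


def motor_update(motor: MotorState, commanded_mv_per_s: float,
                 constraint: Optional[float], mo: MotorParams,
                 dt: float = DT_BODY) -> MotorState:
    """Advance one motor by one body tick.

    ``constraint`` is the externally imposed actual angle (ground or
    anchor), or None for a free joint (the actual angle then follows the
    desired angle).
    """
    motor.desired += commanded_mv_per_s * dt
    motor.desired += (motor.actual - motor.desired) * dt / mo.tau_spring_relax
    # the elastic element has a finite deflection range
    motor.desired = max(motor.actual - mo.max_deflection,
                        min(motor.actual + mo.max_deflection, motor.desired))
    if constraint is None:
        motor.actual = max(0.0, min(50.0, motor.desired))
    else:
        motor.actual = max(0.0, min(50.0, constraint))
    return motor


def beta_spring_for(leg_id: str, mo: MotorParams) -> float:
    if leg_id.startswith("F"):
        return mo.spring_beta_front
    if leg_id.startswith("M"):
        return mo.spring_beta_middle
    return mo.spring_beta_hind


@dataclass
class LegBodyState:
    motors: Dict[str, MotorState]
    contact: bool = False
    intervention: str = "normal"
    anchor: Optional[Tuple[float, float, float]] = None  # world-frame foot
    slipped: bool = False
    frozen_sensors: Optional[SensorFrame] = None

    def mv(self) -> Dict[str, float]:
        return {j: self.motors[j].actual for j in JOINTS}


@dataclass
class BodyState:
    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0  # rad, CCW; +x is forward at heading 0
    height: float = 0.44
    legs: Dict[str, LegBodyState] = field(default_factory=dict)
    time: float = 0.0

    def body_to_world(self, px: float, py: float) -> Tuple[float, float]:
        c, s = math.cos(self.heading), math.sin(self.heading)
        return self.x + c * px - s * py, self.y + s * px + c * py

    def world_to_body(self, wx: float, wy: float) -> Tuple[float, float]:
        c, s = math.cos(self.heading), math.sin(self.heading)
        dx, dy = wx - self.x, wy - self.y
        return c * dx + s * dy, -s * dx + c * dy


class BodyWorld:
    """Closed-loop body surrogate stepping at 100 Hz."""

    def __init__(self, params: Optional[ControllerParams] = None) -> None:
        self.p = params or default_params()
        self.geom = make_geometry(self.p)
        self.state = BodyState()

    # -- construction -----------------------------------------------------

    def init_posture(self, posture_mv: Dict[str, Dict[str, float]]) -> None:
        """Place all legs, set body height so that all feet touch ground."""
        mo = self.p.motor
        legs: Dict[str, LegBodyState] = {}
        drops = []
        for lid in LEG_IDS:
            mv = posture_mv[lid]
            motors = {
                "alpha": MotorState(mo.spring_alpha, mv["alpha"], mv["alpha"]),
                "beta": MotorState(beta_spring_for(lid, mo),
                                   mv["beta"], mv["beta"]),
                "gamma": MotorState(mo.spring_gamma, mv["gamma"], mv["gamma"]),
            }
            legs[lid] = LegBodyState(motors=motors, contact=True)
            g = self.geom[lid]
            _, b_deg, gt_deg = g.angles_deg(mv)
            drops.append(
                g.g.len_tibia * math.cos(math.radians(gt_deg))
                - g.g.len_femur * math.sin(math.radians(b_deg))
            )
        self.state = BodyState(height=float(np.mean(drops)), legs=legs)
        for lid in LEG_IDS:
            self._anchor_leg(lid)

    def _anchor_leg(self, lid: str) -> None:
        leg = self.state.legs[lid]
        fx, fy, fz = forward_kinematics(self.geom[lid], leg.mv(),
                                        self.state.height)
        wx, wy = self.state.body_to_world(fx, fy)
        leg.anchor = (wx, wy, 0.0)
        leg.contact = True

    # -- interventions -----------------------------------------------------

    def apply_intervention(self, leg_id: str, kind: str) -> None:
        if kind not in INTERVENTIONS:
            raise ValueError(f"unknown intervention {kind!r}")
        leg = self.state.legs[leg_id]
        leg.intervention = kind
        if kind == "deafferented_frozen":
            leg.frozen_sensors = SensorFrame(
                alpha=leg.motors["alpha"].actual,
                beta=leg.motors["beta"].actual,
                gamma=leg.motors["gamma"].actual,
                load=0.0, contact=True,
            )
            leg.contact = True
        elif kind == "fixed_standing":
            self._anchor_leg(leg_id)
        elif kind == "treadmill":
            leg.anchor = None
        else:
            leg.frozen_sensors = None

    # -- per-tick update ---------------------------------------------------

    def contact_update(self) -> Dict[str, bool]:
        return {lid: leg.contact for lid, leg in self.state.legs.items()}

    def world_step(self, commands: Dict[str, Dict[str, float]],
                   modes: Dict[str, str]) -> Dict[str, SensorFrame]:
        """One 10 ms cycle: motors, contact, consensus motion, sensors.

        ``commands``: per-leg sensor-space joint velocity commands (mV/s);
        ``modes``: per-leg "swing"/"stance" from the controllers.
        """
        st = self.state
        mo = self.p.motor

        propelling = [
            lid for lid in LEG_IDS
            if (st.legs[lid].intervention == "normal"
                and modes[lid] == "stance" and st.legs[lid].contact
                and st.legs[lid].anchor is not None)
        ]

        # -- consensus body motion from the propelling stance legs
        vx = vy = om = vz = 0.0
        if propelling:
            rows: List[List[float]] = []
            rhs: List[float] = []
            dzs: List[float] = []
            for lid in propelling:
                leg = st.legs[lid]
                g = self.geom[lid]
                mv = leg.mv()
                ux, uy, uz = _mv_rate_to_body_jacobian(g, mv, commands[lid])
                fx, fy, _ = forward_kinematics(g, mv, st.height)
                rows.append([1.0, 0.0, -fy])
                rhs.append(-ux)
                rows.append([0.0, 1.0, fx])
                rhs.append(-uy)
                dzs.append(-uz)  # foot down relative body = body up
            A = np.asarray(rows)
            b = np.asarray(rhs)
            try:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                vx, vy, om = (float(v) for v in sol)
            except np.linalg.LinAlgError:
                vx = float(np.mean(b[0::2]))
                vy = float(np.mean(b[1::2]))
                om = 0.0
            vz = float(np.mean(dzs))

        # -- integrate pose
        c, s = math.cos(st.heading), math.sin(st.heading)
        st.x += (c * vx - s * vy) * DT_BODY
        st.y += (s * vx + c * vy) * DT_BODY
        st.heading += om * DT_BODY
        st.height = max(0.15, st.height + vz * DT_BODY)
        st.time += DT_BODY

        # -- per-leg joint updates
        sensors: Dict[str, SensorFrame] = {}
        for lid in LEG_IDS:
            leg = st.legs[lid]
            g = self.geom[lid]
            if leg.intervention == "deafferented_frozen":
                sensors[lid] = leg.frozen_sensors  # type: ignore[assignment]
                continue

            cmd = commands[lid]
            constrained: Dict[str, Optional[float]] = {j: None for j in JOINTS}

            anchored = (
                leg.anchor is not None
                and (leg.intervention == "fixed_standing"
                     or (modes[lid] == "stance" and leg.contact))
            )
            if anchored and leg.intervention != "treadmill":
                bx, by = st.world_to_body(leg.anchor[0], leg.anchor[1])
                mv_ik, reached = inverse_kinematics(
                    g, (bx, by, leg.anchor[2]), st.height,
                    leg.motors["beta"].actual,
                )
                leg.slipped = not reached
                if not reached:
                    # nearest posture; move the anchor to the actual foot
                    fx, fy, fz = forward_kinematics(g, mv_ik, st.height)
                    wx, wy = st.body_to_world(fx, fy)
                    leg.anchor = (wx, wy, 0.0)
                for j in JOINTS:
                    constrained[j] = mv_ik[j]
                leg.contact = True
            else:
                # free leg (swing, or treadmill stance): track commands,
                # with the ground clamping the beta joint
                mv_now = leg.mv()
                cand_beta = mv_now["beta"] + cmd["beta"] * DT_BODY
                cand = {
                    "alpha": mv_now["alpha"] + cmd["alpha"] * DT_BODY,
                    "beta": cand_beta,
                    "gamma": mv_now["gamma"] + cmd["gamma"] * DT_BODY,
                }
                cand = {k: max(0.0, min(50.0, v)) for k, v in cand.items()}
                _, _, fz = forward_kinematics(g, cand, st.height)
                if fz <= 0.0:
                    beta_ground = self._beta_at_ground(g, cand["gamma"])
                    if beta_ground is not None and cand_beta < beta_ground:
                        constrained["beta"] = beta_ground
                    leg.contact = True
                else:
                    leg.contact = False
                    leg.anchor = None

            for j in JOINTS:
                motor_update(leg.motors[j], cmd[j], constrained[j], mo)

            # a swing leg that just gained ground contact and then enters
            # stance gets anchored at its current foot point
            if (leg.contact and leg.anchor is None
                    and leg.intervention == "normal"):
                self._anchor_leg(lid)

            load = max(
                0.0,
                leg.motors["beta"].spring_k
                * (leg.motors["beta"].actual - leg.motors["beta"].desired),
            )
            sensors[lid] = SensorFrame(
                alpha=leg.motors["alpha"].actual,
                beta=leg.motors["beta"].actual,
                gamma=leg.motors["gamma"].actual,
                load=load,
                contact=leg.contact,
            )
        return sensors

    def _beta_at_ground(self, g: LegGeometry, gamma_mv: float
                        ) -> Optional[float]:
        """Beta sensor value placing the foot exactly on the ground."""
        gg = g.g
        gt = math.radians(gg.gamma_deg_off + gg.gamma_deg_per_mv * gamma_mv)
        sin_b = (gg.len_tibia * math.cos(gt) - self.state.height) / gg.len_femur
        if abs(sin_b) > 1.0:
            return None
        beta_deg = math.degrees(math.asin(sin_b))
        return max(0.0, min(50.0, _deg_to_mv(g, "beta", beta_deg)))

    # -- observables -------------------------------------------------------

    def foot_world(self, lid: str) -> Tuple[float, float, float]:
        leg = self.state.legs[lid]
        fx, fy, fz = forward_kinematics(self.geom[lid], leg.mv(),
                                        self.state.height)
        wx, wy = self.state.body_to_world(fx, fy)
        return wx, wy, fz

    def torque_proxies(self, lid: str) -> Dict[str, float]:
        return {j: self.state.legs[lid].motors[j].torque_proxy for j in JOINTS}
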