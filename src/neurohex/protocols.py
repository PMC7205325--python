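"""Executable experiment protocols.

Each protocol is a self-contained closed-loop simulation described by an
:class:`ExperimentConfig`: forward/backward walking across the velocity
grid, curve walking with per-leg direction codes and velocity factors,
pilocarpine treatment of deafferented ganglia, single-leg treadmill
walking against pilocarpine-driven ganglia, and standing-leg/force-
transducer configurations.  Runs are deterministic given their
configuration; a seed only enters through optional start-posture jitter.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .body_world import DT_BODY, NEURAL_PER_BODY, BodyWorld
from .coordination import CoordinationEngine, build_topology
from .leg_controller import LEG_IDS, LegController, SensorFrame
from .params import ControllerParams, default_params

PROTOCOLS = ("forward", "backward", "curve", "pilocarpine", "treadmill",
             "standing")
VELOCITY_GRID = (8.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0)
GANGLIA = {"pro": ("FL", "FR"), "meso": ("ML", "MR"), "meta": ("HL", "HR")}

# thresholds used when footfall bars are derived from motor-neuron output
DEPRESSOR_BAR_THRESHOLD = 0.0   # deafferented runs: depressor > 0 mV
RETRACTOR_BAR_THRESHOLD = 7.0   # standing-leg runs: retractor > 7 mV


@dataclass
class CurveParams:
    """Parameter set for the curve-walking protocol (75-degree turn)."""

    theta_inner_front: int = 5     # spatial code; 75 (+/- 7.5) degrees
    theta_outer_front: int = 1     # inner theta reduced by a factor of 0.25
    aep_inner_front: Tuple[float, float] = (20.0, 20.0)  # alpha, gamma mV
    aep_outer_front: Tuple[float, float] = (50.0, 45.0)
    vel_factor_inner: Tuple[float, float, float] = (0.75, 0.35, 0.1)
    vel_factor_outer: float = 1.0
    inner_side: str = "L"          # turn toward the left
    global_velocity: float = 45.0


@dataclass
class ExperimentConfig:
    protocol: str = "forward"
    velocity_mV: float = 30.0
    duration_s: float = 80.0
    start_posture: str = "default"
    disturbances: List[Tuple[str, float, float]] = field(default_factory=list)
    interventions: Dict[str, str] = field(default_factory=dict)
    ganglia_treated: Set[str] = field(default_factory=set)
    pilo_mV: float = 25.0
    pilo_stagger_s: float = 0.25   # onset stagger between legs (perfusion)
    curve: Optional[CurveParams] = None
    walking_leg: Optional[str] = None       # treadmill protocol
    standing_legs: Tuple[str, ...] = ()     # standing protocol
    velocity_schedule: List[Tuple[float, float]] = field(default_factory=list)
    seed: Optional[int] = None
    posture_jitter_mV: float = 0.0
    params: ControllerParams = field(default_factory=default_params)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not 0.0 <= self.velocity_mV <= 50.0:
            raise ValueError("velocity_mV must lie in [0, 50]")


def make_start_configuration(name: str = "default",
                             seed: Optional[int] = None,
                             jitter_mV: float = 0.0
                             ) -> Dict[str, Dict[str, float]]:
    """Initial joint sensor values (mV) per leg.

    ``default`` is a near-tripod stance posture: one tripod close to its
    anterior extreme position, the other mid-stance.  ``symmetric`` places
    all legs at the same position (a stress posture from which the
    coordination rules must break symmetry).
    """
    beta0, gamma0 = 18.0, 32.0
    if name == "default":
        alphas = {"FL": 40.0, "MR": 38.0, "HL": 40.0,
                  "FR": 24.0, "ML": 22.0, "HR": 24.0}
    elif name == "symmetric":
        alphas = {lid: 30.0 for lid in LEG_IDS}
    else:
        raise KeyError(f"unknown start posture {name!r}")
    posture = {
        lid: {"alpha": a, "beta": beta0, "gamma": gamma0}
        for lid, a in alphas.items()
    }
    if jitter_mV > 0.0:
        rng = np.random.RandomState(seed if seed is not None else 0)
        for lid in LEG_IDS:
            for j in posture[lid]:
                posture[lid][j] = float(np.clip(
                    posture[lid][j] + rng.uniform(-jitter_mV, jitter_mV),
                    0.0, 50.0,
                ))
    return posture


def list_fixtures() -> List[str]:
    return ["default", "symmetric"]


def schedule_disturbance(config: ExperimentConfig, leg: str,
                         t_start: float, t_end: float) -> ExperimentConfig:
    """Add a prolonged-swing disturbance (swing held, contact ignored)."""
    if not 0.0 <= t_start < t_end <= config.duration_s:
        raise ValueError("disturbance interval outside the run")
    for l, a, b in config.disturbances:
        if l == leg and a < t_end and t_start < b:
            raise ValueError(f"overlapping disturbances on {leg}")
    cfg = copy.deepcopy(config)
    cfg.disturbances.append((leg, t_start, t_end))
    return cfg


def configure_pilocarpine(config: ExperimentConfig,
                          ganglia: Set[str]) -> ExperimentConfig:
    """All legs deafferented and frozen; tonic premotor drive in ``ganglia``."""
    if not ganglia:
        raise ValueError("at least one ganglion must be treated")
    unknown = ganglia - set(GANGLIA)
    if unknown:
        raise ValueError(f"unknown ganglia: {unknown}")
    cfg = copy.deepcopy(config)
    cfg.protocol = "pilocarpine"
    cfg.ganglia_treated = set(ganglia)
    cfg.interventions = {lid: "deafferented_frozen" for lid in LEG_IDS}
    return cfg


def configure_treadmill_single_leg(config: ExperimentConfig,
                                   walking_leg: str,
                                   velocity: float) -> ExperimentConfig:
    if walking_leg not in LEG_IDS:
        raise ValueError(f"unknown leg {walking_leg!r}")
    cfg = copy.deepcopy(config)
    cfg.protocol = "treadmill"
    cfg.walking_leg = walking_leg
    cfg.velocity_mV = velocity
    cfg.ganglia_treated = set(GANGLIA)
    cfg.interventions = {
        lid: ("treadmill" if lid == walking_leg else "deafferented_frozen")
        for lid in LEG_IDS
    }
    return cfg


def configure_standing_legs(config: ExperimentConfig,
                            standing: Sequence[str]) -> ExperimentConfig:
    standing = tuple(standing)
    walking = [lid for lid in LEG_IDS if lid not in standing]
    if len(walking) < 3:
        raise ValueError("at least three walking legs are required")
    cfg = copy.deepcopy(config)
    cfg.protocol = "standing"
    cfg.standing_legs = standing
    cfg.interventions = {
        lid: ("fixed_standing" if lid in standing else "treadmill")
        for lid in LEG_IDS
    }
    return cfg


# ---------------------------------------------------------------------------
# run result
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: ExperimentConfig
    trace: pd.DataFrame  # one row per 10 ms body tick

    def to_csv(self, path: str) -> None:
        self.trace.to_csv(path, index=False)


_VEL_FACTORS_LEG: Dict[str, float] = {}


def _leg_curve_settings(cp: CurveParams) -> Dict[str, Dict[str, float]]:
    inner = cp.inner_side
    outer = "R" if inner == "L" else "L"
    fi, mi, hi = cp.vel_factor_inner
    settings: Dict[str, Dict[str, float]] = {}
    for lid in LEG_IDS:
        side = lid[1]
        rank = lid[0]  # F/M/H
        s: Dict[str, float] = {"theta": 0, "factor": cp.vel_factor_outer}
        if side == inner:
            s["factor"] = {"F": fi, "M": mi, "H": hi}[rank]
            if rank == "F":
                s["theta"] = cp.theta_inner_front
                s["aep_alpha"], s["aep_gamma"] = cp.aep_inner_front
        else:
            if rank == "F":
                s["theta"] = cp.theta_outer_front
                s["aep_alpha"], s["aep_gamma"] = cp.aep_outer_front
        settings[lid] = s
    return settings


def run_protocol(config: ExperimentConfig) -> RunResult:
    """Run one full closed-loop simulation and return the logged trace."""
    p = config.params
    direction = "backward" if config.protocol == "backward" else "forward"
    topo = build_topology(direction, p)
    engine = CoordinationEngine(topo)

    legs: Dict[str, LegController] = {
        lid: LegController(lid, p, direction=direction) for lid in LEG_IDS
    }
    body = BodyWorld(p)
    posture = make_start_configuration(
        config.start_posture, config.seed, config.posture_jitter_mV)
    body.init_posture(posture)

    treadmill_legs: Set[str] = set()
    for lid, kind in config.interventions.items():
        body.apply_intervention(lid, kind)
        if kind == "deafferented_frozen":
            legs[lid].deafferented = True
            legs[lid].force_stance = True
        elif kind == "treadmill":
            treadmill_legs.add(lid)
            body.state.legs[lid].anchor = None
        elif kind == "fixed_standing":
            legs[lid].standing = True

    pilo_legs: List[str] = []
    for gang in sorted(config.ganglia_treated):
        pilo_legs.extend(
            lid for lid in GANGLIA[gang] if legs[lid].deafferented
        )
    # deterministic perfusion stagger in a fixed leg order
    pilo_onset = {
        lid: i * config.pilo_stagger_s
        for i, lid in enumerate(l for l in LEG_IDS if l in pilo_legs)
    }

    curve_settings = (
        _leg_curve_settings(config.curve) if config.curve else None
    )
    if curve_settings:
        for lid, s in curve_settings.items():
            legs[lid].theta_code = int(s["theta"])
            if "aep_alpha" in s:
                legs[lid].swing_target_alpha = s["aep_alpha"]
                legs[lid].swing_target_gamma = s["aep_gamma"]

    vel_sched = sorted(config.velocity_schedule)
    velocity = config.velocity_mV

    n_body = int(round(config.duration_s / DT_BODY))
    sensors: Dict[str, SensorFrame] = {
        lid: SensorFrame(
            alpha=posture[lid]["alpha"], beta=posture[lid]["beta"],
            gamma=posture[lid]["gamma"], contact=True,
        )
        for lid in LEG_IDS
    }
    for lid in LEG_IDS:
        leg_body = body.state.legs[lid]
        if leg_body.frozen_sensors is not None:
            sensors[lid] = leg_body.frozen_sensors

    rows: List[Dict[str, float]] = []
    mn_keys = [("alpha", "ret"), ("alpha", "pro"),
               ("beta", "dep"), ("beta", "lev")]

    for k in range(n_body):
        t = k * DT_BODY
        for ts, tv in vel_sched:
            if t >= ts:
                velocity = tv
        for lid in LEG_IDS:
            fac = curve_settings[lid]["factor"] if curve_settings else 1.0
            legs[lid].vel_local = velocity * fac
            dist = any(
                l == lid and a <= t < b for l, a, b in config.disturbances
            )
            legs[lid].force_swing = dist
            if lid in pilo_onset and t >= pilo_onset[lid]:
                legs[lid].pilo = {
                    j: (config.pilo_mV, config.pilo_mV)
                    for j in ("alpha", "beta", "gamma")
                }

        for _ in range(NEURAL_PER_BODY):
            coord = engine.step(legs, sensors, treadmill_legs)
            for lid in LEG_IDS:
                legs[lid].neural_step(sensors[lid], coord[lid])

        commands = {lid: legs[lid].joint_velocity_commands()
                    for lid in LEG_IDS}
        modes = {lid: legs[lid].mode for lid in LEG_IDS}
        sensors = body.world_step(commands, modes)

        row: Dict[str, float] = {
            "time_s": t,
            "body_x": body.state.x, "body_y": body.state.y,
            "body_heading": body.state.heading,
            "body_height": body.state.height,
            "velocity_mV": velocity,
        }
        for lid in LEG_IDS:
            leg = legs[lid]
            sf = sensors[lid]
            row[f"{lid}_swing"] = 1.0 if leg.mode == "swing" else 0.0
            row[f"{lid}_alpha"] = sf.alpha
            row[f"{lid}_beta"] = sf.beta
            row[f"{lid}_gamma"] = sf.gamma
            row[f"{lid}_contact"] = 1.0 if sf.contact else 0.0
            row[f"{lid}_load"] = sf.load
            row[f"{lid}_r5_send"] = max(engine.out5[lid].values())
            for j, s in mn_keys:
                row[f"{lid}_mn_{s}"] = leg.mn_out[(j, s)]
        rows.append(row)

    return RunResult(config=config, trace=pd.DataFrame(rows))
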