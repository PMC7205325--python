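"""Default parameter tables.

The network architecture is fixed by the model; the individual synaptic
weights, set points and thresholds are free parameters.  All of them live
here as plain dataclasses so that every experiment is reproducible from
the configuration alone.  Angles at the joint level are expressed on the
sensor scale (mV, 0..50); the body surrogate owns the linear maps between
sensor mV and joint degrees.

Orientation convention: most leg-level thresholds are defined on the
*oriented* alpha position ``p`` which equals the alpha sensor during
forward walking and its mirror (50 - alpha) during backward walking, so a
single parameter set serves both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict

import yaml


@dataclass
class MotivationParams:
    tonic: float = 25.0          # housekeeping drive to both bistable units, mV
    w_mutual: float = 1.2        # mutual inhibition weight
    Cm: float = 4.5
    pep_trigger: float = 30.0    # forced swing drive at the posterior limit
    load_trigger: float = 40.0   # forced stance drive on ground load
    aep_trigger: float = 40.0    # forced stance drive at the anterior limit


@dataclass
class SwingParams:
    target_p: float = 47.0       # alpha swing set point (oriented mV), beyond AEP
    end_p: float = 45.0          # hard anterior limit terminating swing
    gate_p: float = 27.0         # load may terminate swing only past this
    kp: float = 0.8              # NPPF gain of the alpha/gamma swing branches
    floor: float = 16.0          # feedforward minimum drive while error > eps
    cap: float = 19.0            # premotor drive ceiling during swing
    err_eps: float = 1.0
    gamma_target: float = 26.0   # gamma swing set point (flexion sensor mV)
    pulse_amp: float = 30.0      # levation "disturb" pulse amplitude, mV
    pulse_tau: float = 0.3       # HPF decay of the pulse, s
    short_step_vel: float = 25.0 # below this velocity the pulse scales down
    short_step_min: float = 0.4  # floor of the velocity scaling factor
    touch_amp: float = 25.0      # levator-reflex pulse on touch, mV
    touch_tau: float = 0.25
    descend_margin: float = 4.0  # swing beta set point below stance level, mV


@dataclass
class StanceParams:
    hold_max: float = 14.0       # stance-motivation hold early in stance, mV
    hold_hi_p: float = 32.0      # oriented position where hold starts to decay
    p_min: float = 8.0           # posterior extreme position (hard PEP), mV
    beta_set_nominal: float = 18.0   # nominal stance beta set point, mV
    k_beta: float = 1.2          # NPPF gain of the beta branches
    height_gain: float = 0.5     # divisive-normalization gain of the height net
    gamma_ref: float = 32.0      # flexion sensor at the vertical-tibia reference
    load_threshold: float = 3.0  # beta torque proxy terminating swing, mV
    press_bias: float = 2.0      # tonic depressor drive during stance, mV


@dataclass
class PremotorParams:
    w_pmn_to_inh: float = 2.0    # PMN -> adapting inhibitory unit
    w_inh_to_pmn: float = 2.0    # inhibitory unit -> antagonist PMN
    tau_adapt_a: float = 2.4     # adaptation of the A-side inhibitor, s
    tau_adapt_b: float = 1.35    # adaptation of the B-side inhibitor, s
    tau_adapt_alpha_a: float = 1.1   # alpha-joint stage adapts faster
    tau_adapt_alpha_b: float = 0.8
    pilo_threshold: float = 25.0 # fictive pilo inputs respond to >= this, mV
    Cm: float = 4.5


@dataclass
class RuleParams:
    # rule 1 (ipsilateral, rear -> front): inhibition of receiver swing
    w_1a: float = 26.0
    w_1b: float = 18.0
    tau_1b_cm: float = 120.0     # integrator membrane constant, ms-units
    w_1b_self: float = 0.85
    gate_1b: float = 5.0         # 2i level that fully suppresses 1b
    # rule 2i (ipsilateral, rear -> front): phasic swing excitation
    w_2i: float = 2.8
    sat_2i: float = 5.0          # half-saturation velocity of the 2i drive
    cm_2i_charge: float = 600.0  # charger membrane constant (ms-units)
    tau_2i_hpf: float = 0.5      # the two cascaded HPF stages, s
    # rule 2c (contralateral): position-derivative swing excitation
    w_2c: float = 1.3
    thr_2c: float = 24.0         # sender oriented position threshold, mV
    slope_2c: float = 1.0
    tau_2c: float = 0.5
    # rule 3i (ipsilateral, front -> rear): tonic window excitation
    w_3i: float = 9.0
    thr3i_on: float = 30.0       # window opens when sender p falls below
    thr3i_off: float = 14.0      # window closes below this
    thr3i_vel_slope: float = 0.12  # linear velocity shift of the window
    # rule 3c (contralateral): tonic window excitation, no high-pass
    w_3c: float = 7.0
    thr3c_on: float = 34.0
    thr3c_off: float = 20.0
    thr3c_vel_slope: float = 0.12
    # rule 5 (premotor coupling)
    gain_5_ipsi: float = 0.2
    gain_5_contra: float = 0.1
    thr_5: float = 18.0          # sender PMN signal must exceed this
    k_send: float = 5.0          # slope of the saturating "output 5" unit
    tau_5_send: float = 3.0      # phasic decay of the send unit, s
    relay_ipsi: float = 0.8      # ipsilateral relay attenuation per hop
    relay_contra: float = 0.2    # contralateral relay attenuation
    treadmill_boost: float = 15.0
    treadmill_alpha_thr: float = 25.0
    backward_2c_thr: float = 26.0  # mirrored threshold for backward walking


@dataclass
class MotorParams:
    gain_alpha: float = 3.0      # sensor-mV/s per mV of net MN output
    gain_beta: float = 3.0
    gain_gamma: float = 3.0
    tau_motor: float = 0.06      # first-order tracking lag, s
    spring_beta_front: float = 8.5
    spring_beta_middle: float = 4.5
    spring_beta_hind: float = 8.5
    spring_alpha: float = 6.0
    spring_gamma: float = 6.0
    tau_spring_relax: float = 0.6  # desired-angle windup relaxation, s
    max_deflection: float = 5.0    # elastic element deflection range, mV


@dataclass
class GeometryParams:
    body_length: float = 1.0     # m; reference for trajectory metrics
    mount_x_front: float = 0.375
    mount_x_middle: float = 0.0
    mount_x_hind: float = -0.375
    mount_y_front: float = 0.15
    mount_y_middle: float = 0.18
    mount_y_hind: float = 0.15
    len_coxa: float = 0.05
    len_femur: float = 0.36
    len_tibia: float = 0.40
    # linear sensor maps: deg = off + slope * mV
    alpha_deg_per_mv: float = 1.8    # alpha: 0..50 mV -> -45..+45 deg
    alpha_deg_off: float = -45.0
    beta_deg_per_mv: float = 1.2     # beta: 0..50 mV -> -30..+30 deg
    beta_deg_off: float = -30.0
    gamma_deg_per_mv: float = -2.34  # gamma: 0..50 mV -> +60..-57 deg
    gamma_deg_off: float = 60.0


@dataclass
class ControllerParams:
    motivation: MotivationParams = field(default_factory=MotivationParams)
    swing: SwingParams = field(default_factory=SwingParams)
    stance: StanceParams = field(default_factory=StanceParams)
    premotor: PremotorParams = field(default_factory=PremotorParams)
    rules: RuleParams = field(default_factory=RuleParams)
    motor: MotorParams = field(default_factory=MotorParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ControllerParams":
        doc = yaml.safe_load(text) or {}
        kw: Dict = {}
        for name, sub in (
            ("motivation", MotivationParams),
            ("swing", SwingParams),
            ("stance", StanceParams),
            ("premotor", PremotorParams),
            ("rules", RuleParams),
            ("motor", MotorParams),
            ("geometry", GeometryParams),
        ):
            kw[name] = sub(**doc.get(name, {}))
        return cls(**kw)


def default_params() -> ControllerParams:
    return ControllerParams()
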