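"""Tests for the kinematic body surrogate."""

import math

import numpy as np
import pytest

from neurohex import body_world as bw
from neurohex import protocols
from neurohex.params import default_params


@pytest.fixture()
def geom():
    return bw.make_geometry()


MID = {"alpha": 25.0, "beta": 18.0, "gamma": 32.0}


class TestForwardKinematics:
    def test_reference_posture_is_lateral(self, geom):
        g = geom["ML"]
        fx, fy, fz = bw.forward_kinematics(g, MID, 0.44)
        assert fy > g.mount[1]           # foot lateral of the mount
        assert abs(fx - g.mount[0]) < 0.05

    def test_levation_raises_foot(self, geom):
        g = geom["ML"]
        zs = [bw.forward_kinematics(g, {**MID, "beta": b}, 0.44)[2]
              for b in (10.0, 20.0, 30.0)]
        assert zs[0] < zs[1] < zs[2]

    def test_gamma_changes_leg_extension(self, geom):
        g = geom["ML"]
        def radial(gamma):
            fx, fy, _ = bw.forward_kinematics(g, {**MID, "gamma": gamma}, 0.44)
            return math.hypot(fx - g.mount[0], fy - g.mount[1])
        # less flexion (lower sensor value) extends the leg
        assert radial(20.0) > radial(32.0) > radial(45.0)

    def test_out_of_range_angles(self, geom):
        with pytest.raises(ValueError):
            bw.forward_kinematics(geom["ML"], {**MID, "beta": 60.0}, 0.44)

    def test_ik_round_trip(self, geom):
        g = geom["HL"]
        foot = bw.forward_kinematics(g, MID, 0.44)
        mv, reached = bw.inverse_kinematics(g, foot, 0.44, MID["beta"])
        assert reached
        for j in bw.JOINTS:
            assert mv[j] == pytest.approx(MID[j], abs=1e-6)

    def test_ik_flags_unreachable(self, geom):
        g = geom["ML"]
        mv, reached = bw.inverse_kinematics(g, (3.0, 3.0, 0.0), 0.44, 18.0)
        assert not reached


class TestMotor:
    def test_free_tracking_with_zero_torque(self):
        mo = default_params().motor
        m = bw.MotorState(spring_k=8.5, desired=20.0, actual=20.0)
        for _ in range(100):
            bw.motor_update(m, 10.0, None, mo)
        assert m.actual == pytest.approx(m.desired)
        assert abs(m.torque_proxy) < 1e-9

    def test_blocked_joint_builds_load(self):
        mo = default_params().motor
        m = bw.MotorState(spring_k=8.5, desired=20.0, actual=20.0)
        for _ in range(60):
            bw.motor_update(m, -30.0, 20.0, mo)  # pressed against constraint
        assert m.desired < m.actual
        assert m.torque_proxy < -3.0
        # deflection capped by the elastic range
        assert m.actual - m.desired <= mo.max_deflection + 1e-9

    def test_zero_command_holds(self):
        mo = default_params().motor
        m = bw.MotorState(spring_k=4.5, desired=33.0, actual=33.0)
        for _ in range(50):
            bw.motor_update(m, 0.0, None, mo)
        assert m.actual == pytest.approx(33.0)

    def test_beta_spring_ratio(self):
        mo = default_params().motor
        ks = [bw.beta_spring_for(lid, mo) for lid in ("FL", "ML", "HL")]
        assert ks == [8.5, 4.5, 8.5]


def _standing_world():
    world = bw.BodyWorld()
    posture = protocols.make_start_configuration("default")
    world.init_posture(posture)
    return world


class TestWorldStep:
    def test_tick_counts(self):
        assert bw.NEURAL_PER_BODY * bw.DT_BODY * 1000 == pytest.approx(100.0)
        # 1 s of simulation = 100 body ticks and 1000 neural ticks

    def test_identical_rearward_commands_translate_body(self):
        world = _standing_world()
        cmds = {lid: {"alpha": -10.0, "beta": 0.0, "gamma": 0.0}
                for lid in bw.LEG_IDS}
        modes = {lid: "stance" for lid in bw.LEG_IDS}
        for _ in range(50):
            world.world_step(cmds, modes)
        assert world.state.x > 0.03          # retraction propels forward
        assert abs(world.state.y) < 0.02
        assert abs(world.state.heading) < 0.05

    def test_asymmetric_commands_yaw_body(self):
        world = _standing_world()
        cmds = {lid: {"alpha": -4.0 if lid.endswith("L") else -16.0,
                      "beta": 0.0, "gamma": 0.0} for lid in bw.LEG_IDS}
        modes = {lid: "stance" for lid in bw.LEG_IDS}
        for _ in range(50):
            world.world_step(cmds, modes)
        assert world.state.heading > 0.01    # slower left side: turn left

    def test_zero_commands_keep_body_stationary(self):
        world = _standing_world()
        cmds = {lid: {"alpha": 0.0, "beta": 0.0, "gamma": 0.0}
                for lid in bw.LEG_IDS}
        modes = {lid: "stance" for lid in bw.LEG_IDS}
        for _ in range(30):
            world.world_step(cmds, modes)
        assert abs(world.state.x) < 1e-9 and abs(world.state.y) < 1e-9

    def test_unknown_intervention_rejected(self):
        world = _standing_world()
        with pytest.raises(ValueError):
            world.apply_intervention("ML", "levitate")

    def test_deafferented_leg_reports_frozen_sensors(self):
        world = _standing_world()
        world.apply_intervention("ML", "deafferented_frozen")
        cmds = {lid: {"alpha": -10.0, "beta": 0.0, "gamma": 0.0}
                for lid in bw.LEG_IDS}
        modes = {lid: "stance" for lid in bw.LEG_IDS}
        before = None
        for _ in range(20):
            sensors = world.world_step(cmds, modes)
            if before is None:
                before = sensors["ML"].alpha
        assert sensors["ML"].alpha == before


@pytest.fixture(scope="module")
def short_run():
    cfg = protocols.ExperimentConfig(
        protocol="forward", velocity_mV=30.0, duration_s=20.0
    )
    return protocols.run_protocol(cfg)


class TestClosedLoopInvariants:

    def test_determinism_bit_identical(self, short_run):
        cfg = protocols.ExperimentConfig(
            protocol="forward", velocity_mV=30.0, duration_s=20.0
        )
        again = protocols.run_protocol(cfg)
        assert short_run.trace.equals(again.trace)

    def test_height_regulated_near_reference(self, short_run):
        h = short_run.trace.query("time_s > 5")["body_height"]
        assert 0.38 < h.min() and h.max() < 0.52

    def test_sensor_outputs_in_range(self, short_run):
        tr = short_run.trace
        for lid in bw.LEG_IDS:
            for j in ("alpha", "beta", "gamma"):
                col = tr[f"{lid}_{j}"]
                assert col.min() >= 0.0 and col.max() <= 50.0
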