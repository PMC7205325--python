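"""Tests for the single-leg controller."""

import numpy as np
import pytest

from neurohex import leg_controller as lc
from neurohex import protocols
from neurohex.neuron_core import check_dale
from neurohex.params import default_params


class TestMotivation:
    def test_state_persists_without_drive(self):
        pair = lc.MotivationPair(default_params(), active="swing")
        for _ in range(1000):
            state = lc.motivation_step(pair, 0.0, 0.0)
        assert state.swing_act > state.stance_act

    def test_dominant_drive_flips_state(self):
        pair = lc.MotivationPair(default_params(), active="swing")
        flipped_at = None
        for k in range(500):
            state = lc.motivation_step(pair, 0.0, 40.0)
            if state.stance_act > state.swing_act:
                flipped_at = k
                break
        assert flipped_at is not None and flipped_at < 200

    def test_hysteresis_under_symmetric_drive(self):
        pair = lc.MotivationPair(default_params(), active="swing")
        for _ in range(1000):
            state = lc.motivation_step(pair, 20.0, 20.0)
        assert state.swing_act > state.stance_act

    def test_negative_drive_rejected(self):
        pair = lc.MotivationPair(default_params())
        with pytest.raises(ValueError):
            lc.motivation_step(pair, -1.0, 0.0)


class TestHeightNet:
    def test_reference_returns_nominal(self):
        p = default_params()
        assert lc.height_net_eval(p.stance.gamma_ref, p) == pytest.approx(
            p.stance.beta_set_nominal
        )

    def test_smooth_over_working_range(self):
        vals = [lc.height_net_eval(g) for g in np.linspace(28.0, 36.0, 50)]
        steps = np.abs(np.diff(vals))
        assert steps.max() < 0.2  # no discontinuity

    def test_divisive_scaling(self):
        p = default_params()
        st = p.stance
        g1, g2 = 36.0, 40.0
        ratio = lc.height_net_eval(g2, p) / lc.height_net_eval(g1, p)
        expected = (1 + st.height_gain * abs(g1 - st.gamma_ref) / 50) / (
            1 + st.height_gain * abs(g2 - st.gamma_ref) / 50
        )
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_sensor(self):
        with pytest.raises(ValueError):
            lc.height_net_eval(51.0)


def _run_stage(drive_a, drive_b, seconds=40.0, pilo=True):
    stage = lc.PremotorStage(default_params())
    n = int(seconds * 1000)
    a = np.empty(n)
    b = np.empty(n)
    for k in range(n):
        if pilo:
            a[k], b[k] = stage.step(0.0, 0.0, pilo_a=drive_a, pilo_b=drive_b)
        else:
            a[k], b[k] = stage.step(drive_a, drive_b)
    return a, b


def _oscillates(x, thr=0.5, t0=15_000):
    y = x[t0:] > thr
    onsets = np.flatnonzero(~y[:-1] & y[1:])
    return len(onsets) >= 3


class TestPremotorStage:
    def test_oscillates_with_bilateral_tonic_drive(self):
        a, b = _run_stage(25.0, 25.0)
        assert _oscillates(a) and _oscillates(b)

    def test_single_branch_drive_is_tonic(self):
        a, b = _run_stage(25.0, 0.0)
        assert not _oscillates(a)
        assert a[-1] > 20.0 and b[-1] < 0.5

    def test_silent_without_drive(self):
        a, b = _run_stage(0.0, 0.0)
        assert a[-1] < 1e-6 and b[-1] < 1e-6

    def test_subthreshold_pilo_ignored(self):
        # the fictive pilo inputs respond only to strong activation
        a, b = _run_stage(20.0, 20.0)
        assert not _oscillates(a) and a[-1] < 1e-6

    def test_co_contraction_suppressed_below_threshold(self):
        # ordinary branch drives (not through the pilo gate): the stronger
        # branch wins and the antagonist stays near zero
        a, b = _run_stage(12.0, 4.0, seconds=5.0, pilo=False)
        assert a[-1] > 5.0
        assert b[-1] < 1.0


class TestBuildLegController:
    def test_network_passes_dale_and_has_expected_scale(self):
        net, ctrl = lc.build_leg_controller("FL")
        assert check_dale(net) == []
        census = lc.unit_census(net)
        assert census["total"] > 120  # motivation+branches+ring+coordination
        assert census["ring"] == 64   # 5 x 12 layers plus O1..O4

    def test_identical_architecture_across_legs(self):
        censuses = []
        for lid in lc.LEG_IDS:
            net, _ = lc.build_leg_controller(lid)
            censuses.append(lc.unit_census(net))
        assert all(c == censuses[0] for c in censuses)

    def test_invalid_leg_id(self):
        with pytest.raises(ValueError):
            lc.build_leg_controller("XX")


class TestSwingBehaviour:
    def test_levation_pulse_scales_down_at_low_velocity(self):
        p = default_params()
        outs = {}
        for vel in (8.0, 50.0):
            ctrl = lc.LegController("ML", p, start_mode="swing")
            ctrl.vel_local = vel
            sens = lc.SensorFrame(alpha=10.0, beta=16.0, gamma=32.0)
            peak = 0.0
            for _ in range(400):
                drives = ctrl.swing_drives(sens)
                peak = max(peak, drives[("beta", "lev")])
            outs[vel] = peak
        assert outs[8.0] < 0.7 * outs[50.0]

    def test_touch_elicits_retraction_with_levation(self):
        ctrl = lc.LegController("ML", start_mode="swing")
        ctrl.vel_local = 30.0
        sens = lc.SensorFrame(alpha=25.0, beta=20.0, gamma=32.0, touch=True)
        for _ in range(600):
            drives = ctrl.swing_drives(sens)
        drives = ctrl.swing_drives(sens)
        assert drives[("alpha", "ret")] > 0.0
        assert drives[("beta", "lev")] > 0.0


class TestPhaseTransitions:
    def _leg(self, mode="swing"):
        ctrl = lc.LegController("ML", start_mode=mode)
        ctrl.vel_local = 30.0
        return ctrl

    def test_load_before_gate_does_not_terminate_swing(self):
        ctrl = self._leg()
        sens = lc.SensorFrame(alpha=15.0, beta=16.0, gamma=32.0,
                              load=10.0, contact=True)
        sw, st = ctrl.transition_drives(sens, lc.CoordIn())
        assert st == 0.0

    def test_load_after_gate_terminates_swing(self):
        ctrl = self._leg()
        ctrl.gate_passed = True
        ctrl.lifted = True
        sens = lc.SensorFrame(alpha=35.0, beta=16.0, gamma=32.0,
                              load=10.0, contact=True)
        sw, st = ctrl.transition_drives(sens, lc.CoordIn())
        assert st >= default_params().motivation.load_trigger

    def test_posterior_extreme_forces_swing(self):
        ctrl = self._leg(mode="stance")
        sens = lc.SensorFrame(alpha=5.0, beta=16.0, gamma=32.0, contact=True)
        sw, st = ctrl.transition_drives(sens, lc.CoordIn())
        assert sw >= default_params().motivation.pep_trigger


class TestDecentralization:
    def test_legs_step_without_any_coordination(self):
        # all rule weights zeroed: every leg still free-runs its own cycle
        p = default_params()
        for attr in ("w_1a", "w_1b", "w_2i", "w_2c", "w_3i", "w_3c",
                     "gain_5_ipsi", "gain_5_contra"):
            setattr(p.rules, attr, 0.0)
        cfg = protocols.ExperimentConfig(
            protocol="forward", velocity_mV=30.0, duration_s=40.0, params=p
        )
        tr = protocols.run_protocol(cfg).trace
        late = tr[tr.time_s > 15.0]
        for lid in lc.LEG_IDS:
            x = late[f"{lid}_swing"].to_numpy()
            onsets = np.flatnonzero((x[:-1] < 0.5) & (x[1:] > 0.5))
            assert len(onsets) >= 3, f"{lid} stopped stepping"
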