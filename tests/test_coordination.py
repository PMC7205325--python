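"""Tests for the interleg coordination rules and topology."""

import numpy as np
import pytest

from neurohex import coordination as co
from neurohex.neuron_core import BasicUnit, HighpassUnit, IntegratorUnit
from neurohex.params import default_params


def _rp():
    return default_params().rules


def _chan_2i(rp):
    return co.RuleChannel(
        rule="2i", sender="HL", receiver="ML",
        charger=BasicUnit(Cm=rp.cm_2i_charge),
        hpf1=HighpassUnit(tau_fall=rp.tau_2i_hpf),
        hpf2=HighpassUnit(tau_fall=rp.tau_2i_hpf),
    )


class TestTopology:
    def test_forward_channel_sets(self):
        topo = co.build_topology("forward")
        rules = {}
        for s, r, rule, _ in topo.edge_list():
            rules.setdefault(rule, []).append((s, r))
        assert set(rules["1"]) == set(co.IPSI_REAR_TO_FRONT)
        assert set(rules["2i"]) == set(co.IPSI_REAR_TO_FRONT)
        assert set(rules["3i"]) == set(co.IPSI_FRONT_TO_REAR)
        # no contralateral rule 1 anywhere
        assert all(s[1] == r[1] for s, r in rules["1"])
        # 5ch exactly once per direction between the hind legs
        assert sorted(rules["5ch"]) == [("HL", "HR"), ("HR", "HL")]
        # rule 5 covers all neighbor pairs except hind-hind
        assert ("HL", "HR") not in rules["5c"]
        assert ("FL", "FR") in rules["5c"] and ("ML", "MR") in rules["5c"]

    def test_backward_subset(self):
        topo = co.build_topology("backward")
        present = {c.rule for c in topo.channels}
        assert present == {"1", "2i", "2c"}

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            co.build_topology("sideways")

    def test_rule5_gain_ratio(self):
        topo = co.build_topology("forward")
        gains = {c.rule: c.gain for c in topo.channels}
        assert gains["5i"] / gains["5c"] == pytest.approx(2.0)

    def test_edge_csv(self):
        text = co.build_topology("forward").to_csv()
        assert text.startswith("sender,receiver,rule,gain")
        assert "HL,ML,1," in text


class TestRule1:
    def test_inhibits_while_sender_swings(self):
        rp = _rp()
        ch = co.RuleChannel(rule="1", sender="HL", receiver="ML",
                            integrator=IntegratorUnit(Cm=rp.tau_1b_cm,
                                                      w_self=rp.w_1b_self))
        out = 0.0
        for _ in range(500):
            out = co.rule1_step(ch, None, True, 0.0, rp)
        assert out >= rp.w_1a

    def test_1b_prolongs_inhibition_after_swing_end(self):
        rp = _rp()
        ch = co.RuleChannel(rule="1", sender="HL", receiver="ML",
                            integrator=IntegratorUnit(Cm=rp.tau_1b_cm,
                                                      w_self=rp.w_1b_self))
        for _ in range(800):
            co.rule1_step(ch, None, True, 0.0, rp)
        out_after = co.rule1_step(ch, None, False, 0.0, rp)
        assert 0.0 < out_after < rp.w_1a + rp.w_1b
        assert out_after > 2.0  # residual inhibition

    def test_2i_suppresses_1b(self):
        rp = _rp()
        ch = co.RuleChannel(rule="1", sender="HL", receiver="ML",
                            integrator=IntegratorUnit(Cm=rp.tau_1b_cm,
                                                      w_self=rp.w_1b_self))
        for _ in range(800):
            co.rule1_step(ch, None, True, 0.0, rp)
        gated = co.rule1_step(ch, None, False, rp.gate_1b, rp)
        assert gated == pytest.approx(0.0)


class TestRule2i:
    def _pulse(self, vel, rp):
        ch = _chan_2i(rp)
        for _ in range(1000):
            co.rule2i_step(ch, False, vel, rp)
        return np.array([co.rule2i_step(ch, True, vel, rp)
                         for _ in range(4000)])

    def test_pulse_after_swing_end(self):
        rp = _rp()
        out = self._pulse(50.0, rp)
        assert out.max() > 10.0
        assert out[-1] < 0.2 * out.max()  # phasic, not tonic

    def test_latency_monotone_in_velocity(self):
        rp = _rp()
        lats = []
        for vel in (10.0, 20.0, 50.0):
            out = self._pulse(vel, rp)
            above = np.flatnonzero(out > 8.0)
            lats.append(above[0] if len(above) else len(out))
        assert lats[0] >= lats[1] >= lats[2]

    def test_weaker_at_lower_velocity(self):
        rp = _rp()
        assert self._pulse(10.0, rp).max() < self._pulse(50.0, rp).max()


class TestRule2c:
    def test_constant_position_decays_to_zero(self):
        rp = _rp()
        ch = co.RuleChannel(rule="2c", sender="FL", receiver="FR",
                            hpf1=HighpassUnit(tau_fall=rp.tau_2c))
        out = 0.0
        for _ in range(30_000):
            out = co.rule2c_step(ch, 10.0, True, rp)
        assert out < 0.05

    def test_crossing_speed_sets_amplitude(self):
        rp = _rp()
        peaks = []
        for rate in (5.0, 25.0):  # mV/s sender retraction speed
            ch = co.RuleChannel(rule="2c", sender="FL", receiver="FR",
                                hpf1=HighpassUnit(tau_fall=rp.tau_2c))
            peak = 0.0
            p = rp.thr_2c + 5.0
            for k in range(4000):
                p -= rate / 1000.0
                peak = max(peak, co.rule2c_step(ch, max(p, 0.0), True, rp))
            peaks.append(peak)
        assert peaks[0] < peaks[1]  # effect fades at low velocity


class TestRule3:
    def test_window_logic(self):
        rp = _rp()
        ch = co.RuleChannel(rule="3i", sender="FL", receiver="ML")
        on = rp.thr3i_on + rp.thr3i_vel_slope * (30.0 - 25.0)
        assert co.rule3_step(ch, on + 5.0, True, 30.0, rp) == 0.0
        assert co.rule3_step(ch, on - 2.0, True, 30.0, rp) == rp.w_3i
        assert co.rule3_step(ch, rp.thr3i_off - 2.0, True, 30.0, rp) == 0.0

    def test_3c_active_at_low_velocity(self):
        rp = _rp()
        ch = co.RuleChannel(rule="3c", sender="FL", receiver="FR")
        on = rp.thr3c_on + rp.thr3c_vel_slope * (8.0 - 25.0)
        assert co.rule3_step(ch, on - 2.0, True, 8.0, rp) == rp.w_3c

    def test_silent_during_sender_swing(self):
        rp = _rp()
        ch = co.RuleChannel(rule="3i", sender="FL", receiver="ML")
        assert co.rule3_step(ch, 25.0, False, 30.0, rp) == 0.0


class TestRule5:
    def test_threshold_gates_send_unit(self):
        rp = _rp()
        assert co.rule5_send(rp.thr_5 - 1.0, rp) == 0.0
        assert co.rule5_send(rp.thr_5 + 5.0, rp) > 0.0

    def test_ipsi_contra_ratio(self):
        rp = _rp()
        send = co.rule5_send(30.0, rp)
        ipsi = co.RuleChannel(rule="5i", sender="HL", receiver="ML",
                              gain=rp.gain_5_ipsi)
        contra = co.RuleChannel(rule="5c", sender="ML", receiver="MR",
                                gain=rp.gain_5_contra)
        vi, _ = co.rule5_step(ipsi, send, rp)
        vc, _ = co.rule5_step(contra, send, rp)
        assert vi / vc == pytest.approx(2.0)

    def test_treadmill_boost_applies_above_alpha_threshold(self):
        rp = _rp()
        weak = 6.0  # normal walking premotor level, below threshold
        assert co.rule5_send(weak, rp) == 0.0
        boosted = co.rule5_send(weak, rp, treadmill_mode=True,
                                sender_alpha_sensor=30.0)
        assert boosted > 50.0  # factor-15 channel
        second_half = co.rule5_send(weak, rp, treadmill_mode=True,
                                    sender_alpha_sensor=20.0)
        assert second_half == 0.0

    def test_5ch_returns_symmetric_magnitudes(self):
        rp = _rp()
        ch = co.RuleChannel(rule="5ch", sender="HL", receiver="HR",
                            gain=rp.gain_5_contra)
        exc, inh = co.rule5ch_step(ch, 40.0, rp)
        assert exc == inh == pytest.approx(rp.gain_5_contra * 40.0)
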