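"""Unit and property tests for the rate-neuron engine."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from neurohex import neuron_core as nc


class TestStepUnit:
    def test_single_step_from_rest(self):
        spec = nc.UnitSpec(id="u")
        out = nc.step_unit(nc.UnitState(), 0.0, 45.0, spec)
        assert out.v == pytest.approx(10.0)
        assert out.output == pytest.approx(10.0)

    def test_decay_without_input(self):
        spec = nc.UnitSpec(id="u")
        out = nc.step_unit(nc.UnitState(v=10.0), 0.0, 0.0, spec)
        assert out.v == pytest.approx(10.0 * (1 - 1 / 4.5))
        assert out.v == pytest.approx(7.778, abs=1e-3)

    def test_converges_to_constant_input(self):
        spec = nc.UnitSpec(id="u")
        s = nc.UnitState()
        for _ in range(200):
            s = nc.step_unit(s, 0.0, 30.0, spec)
        assert s.v == pytest.approx(30.0, abs=1e-6)

    def test_geometric_convergence_rate(self):
        spec = nc.UnitSpec(id="u", Cm=4.5)
        s = nc.UnitState(v=0.0)
        errs = []
        for _ in range(5):
            s = nc.step_unit(s, 0.0, 20.0, spec)
            errs.append(abs(s.v - 20.0))
        ratios = [b / a for a, b in zip(errs, errs[1:])]
        for r in ratios:
            assert r == pytest.approx(1 - 1 / 4.5, abs=1e-9)

    def test_nonfinite_input_raises(self):
        spec = nc.UnitSpec(id="u")
        with pytest.raises(FloatingPointError):
            nc.step_unit(nc.UnitState(), float("nan"), 0.0, spec)


class TestAggregation:
    def test_excitatory_clip_at_80(self):
        e, i = nc.aggregate_synaptic_input(
            [(50.0, 1.0, nc.EXC), (40.0, 1.0, nc.EXC)]
        )
        assert e == 80.0 and i == 0.0

    def test_empty_sum(self):
        assert nc.aggregate_synaptic_input([]) == (0.0, 0.0)

    def test_balanced_input_cancels(self):
        e, i = nc.aggregate_synaptic_input(
            [(30.0, 1.0, nc.EXC), (30.0, 1.0, nc.INH)]
        )
        assert e - i == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            nc.aggregate_synaptic_input([(10.0, -1.0, nc.EXC)])

    def test_presynaptic_inhibition_is_multiplicative(self):
        e_open, _ = nc.aggregate_synaptic_input(
            [(40.0, 1.0, nc.EXC)], presyn_gates=[0.0]
        )
        e_half, _ = nc.aggregate_synaptic_input(
            [(40.0, 1.0, nc.EXC)], presyn_gates=[25.0]
        )
        e_closed, _ = nc.aggregate_synaptic_input(
            [(40.0, 1.0, nc.EXC)], presyn_gates=[50.0]
        )
        assert e_open == pytest.approx(40.0)
        assert e_half == pytest.approx(20.0)
        assert e_closed == pytest.approx(0.0)

    @given(st.lists(st.tuples(
        st.floats(0, 50), st.floats(0, 5),
        st.sampled_from([nc.EXC, nc.INH])), max_size=20))
    @settings(max_examples=50, derandomize=True)
    def test_sums_never_exceed_clip(self, incoming):
        e, i = nc.aggregate_synaptic_input(incoming)
        assert 0.0 <= e <= 80.0 and 0.0 <= i <= 80.0


class TestHighpass:
    def test_step_response_then_slow_decay(self):
        spec = nc.UnitSpec(id="h", kind="highpass", tau_fall=10.0)
        s = nc.UnitState()
        s = nc.step_highpass_unit(s, 30.0, spec)
        peak = s.output
        assert peak == pytest.approx(30.0, rel=0.01)
        for _ in range(10_000):  # 10 s at 1 ms
            s = nc.step_highpass_unit(s, 30.0, spec)
        assert s.output == pytest.approx(30.0 * math.exp(-1.0), rel=0.05)

    def test_dc_rejection(self):
        spec = nc.UnitSpec(id="h", kind="highpass")
        s = nc.UnitState()
        for _ in range(120_000):
            s = nc.step_highpass_unit(s, 30.0, spec)
        assert s.output < 0.01

    def test_fast_recovery_from_below_zero(self):
        spec = nc.UnitSpec(id="h", kind="highpass")
        s = nc.UnitState()
        for _ in range(2000):
            s = nc.step_highpass_unit(s, 30.0, spec)
        s = nc.step_highpass_unit(s, 0.0, spec)
        assert s.v < 0.0 and s.output == 0.0
        for _ in range(100):  # tau_rise = 0.01 s -> recovered within 0.1 s
            s = nc.step_highpass_unit(s, 0.0, spec)
        assert s.v == pytest.approx(0.0, abs=0.5)

    def test_invalid_dt(self):
        spec = nc.UnitSpec(id="h", kind="highpass")
        with pytest.raises(ValueError):
            nc.step_highpass_unit(nc.UnitState(), 1.0, spec, dt=0.0)


def _two_unit_chain():
    units = [
        nc.UnitSpec(id="src"),
        nc.UnitSpec(id="dst"),
    ]
    syn = [nc.SynapseSpec("src", "dst", 1.0)]
    return nc.NetworkSpec(units=units, synapses=syn)


class TestNetwork:
    def test_quiescence(self):
        net = _two_unit_chain()
        states = net.initial_states()
        states = nc.step_network(net, states)
        assert all(s.output == 0.0 for s in states.values())

    def test_chain_converges_to_source(self):
        net = _two_unit_chain()
        states = net.initial_states()
        for _ in range(300):
            states = nc.step_network(net, states, external={"src": 50.0})
        assert states["dst"].output == pytest.approx(50.0, abs=1e-3)

    def test_bit_identical_reruns(self):
        net = _two_unit_chain()
        traces = []
        for _ in range(2):
            states = net.initial_states()
            tr = []
            for k in range(100):
                states = nc.step_network(
                    net, states, external={"src": 13.7 + 0.1 * k}
                )
                tr.append(states["dst"].v)
            traces.append(tr)
        assert traces[0] == traces[1]

    def test_missing_state_raises(self):
        net = _two_unit_chain()
        with pytest.raises(KeyError):
            nc.step_network(net, {"src": nc.UnitState()})

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=50))
    @settings(max_examples=30, derandomize=True)
    def test_outputs_bounded(self, inputs):
        net = _two_unit_chain()
        states = net.initial_states()
        for x in inputs:
            states = nc.step_network(net, states, external={"src": x})
            for s in states.values():
                assert 0.0 <= s.output <= 50.0

    def test_yaml_round_trip(self):
        net = _two_unit_chain()
        net2 = nc.NetworkSpec.from_yaml(net.to_yaml())
        assert [u.id for u in net2.units] == ["src", "dst"]
        assert net2.synapses[0].weight == 1.0

    def test_tables_export(self):
        units, syn = _two_unit_chain().to_tables()
        assert list(units["id"]) == ["src", "dst"]
        assert len(syn) == 1


class TestDale:
    def test_empty_network_clean(self):
        assert nc.check_dale(nc.NetworkSpec()) == []

    def test_clean_chain(self):
        assert nc.check_dale(_two_unit_chain()) == []

    def test_mixed_sign_unit_detected(self):
        # constructed violation: duplicate unit declaration with both signs
        units = [nc.UnitSpec(id="a", sign=nc.EXC),
                 nc.UnitSpec(id="b"), nc.UnitSpec(id="c")]
        syn = [nc.SynapseSpec("a", "b", 1.0), nc.SynapseSpec("a", "c", 1.0)]
        net = nc.NetworkSpec(units=units, synapses=syn)
        # force inconsistent bookkeeping to emulate a mixed unit
        net.units[0] = nc.UnitSpec(id="a", sign=nc.INH)
        sign_map_violation = nc.check_dale(net)
        assert sign_map_violation == []  # sign is per-unit: still consistent
        # a genuine violation requires two sign records for one presynaptic
        # unit; emulate via two unit entries sharing an id is rejected at
        # construction, so the engine structurally enforces Dale's law
        with pytest.raises(ValueError):
            nc.NetworkSpec(units=[nc.UnitSpec(id="a"),
                                  nc.UnitSpec(id="a", sign=nc.INH)])
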