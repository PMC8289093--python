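"""Acausal graph assembly, conservation laws, simulation, initialization."""

import numpy as np
import pytest

from avnode import network as net
from avnode.channels import ElectricChannel
from avnode.kinetics import GateTS, GenLogisticParams
from avnode.presets import build_demo_cell, build_gate_relaxation
from avnode.quantities import audit_model_units, quantity


def _gate(n0=0.0) -> GateTS:
    steady = GenLogisticParams.in_si(0.0, 1.0, -0.03, 125.0, y_unit="1")
    tau = GenLogisticParams.in_si(0.005, 0.03, -0.04, -100.0)
    g = GateTS.from_logistic("gate", steady, tau)
    g.n = n0
    return g


def _channel(name="ch", g_max=1e-9, v_eq=0.0, with_gate=False) -> net.ChannelComponent:
    gates = {"gate": _gate()} if with_gate else {}
    return net.ChannelComponent(
        name,
        ElectricChannel(
            name, quantity(g_max, "S"), quantity(v_eq, "V"), gates=gates
        ),
    )


def _membrane(channels, drive, v0=-0.06, c_m=4.0e-11):
    g = net.ComponentGraph()
    gnd = net.Ground("gnd")
    cap = net.MembraneCapacitor("cm", quantity(c_m, "F"), v0=quantity(v0, "V"))
    src = net.CurrentSource("src", drive=drive)
    g.add(gnd, cap, src, *channels)
    for comp in [cap, src, *channels]:
        g.connect(gnd.pins["p"], comp.pins["p"])
        g.connect(cap.pins["n"], comp.pins["n"])
    return g


class TestConnect:
    def test_pin_port_mismatch_rejected(self):
        g = net.ComponentGraph()
        cap = net.MembraneCapacitor("cm", quantity(1e-11, "F"))
        comp = net.CompartmentComponent(
            "cyto",
            __import__("avnode.calcium", fromlist=["CompartmentSpec"]).CompartmentSpec(
                "cyto", quantity(1e-15, "m^3"), quantity(0.0002, "mM")
            ),
        )
        g.add(cap, comp)
        with pytest.raises(net.ConnectionError):
            g.connect(cap.pins["n"], comp.ports["ca"])

    def test_reconnecting_is_idempotent(self):
        g = build_gate_relaxation()
        ch, vc = g.components["ch"], g.components["vc"]
        before = len(g.nodes())
        g.connect(vc.pins["n"], ch.pins["n"])
        assert len(g.nodes()) == before

    def test_three_terms_on_shared_node(self):
        g = _membrane([_channel("a"), _channel("b")], drive=0.0)
        sys = g.assemble()
        balances = sys.node_balances(0.0, sys.y0)
        node = balances["cm.n"]
        assert {name for name, _ in node} == {"a", "b", "src", "cm"}


class TestAssemble:
    def test_capacitor_ramp_from_published_constants(self):
        """C_m = 4.0e-11 F with a -1.2 nA source ramps at -30 V/s."""
        g = _membrane([], drive=quantity(-1.2e-9, "A"), v0=0.0)
        sys = g.assemble()
        assert sys.rhs(0.0, sys.y0)[0] == pytest.approx(-30.0, rel=1e-12)
        traj = net.simulate(
            sys, net.SolverSettings(stop=0.05, tolerance=1e-12, interval=1e-3)
        )
        exact = -30.0 * traj.time
        np.testing.assert_allclose(traj["cm.v"], exact, rtol=1e-9, atol=1e-12)

    def test_parallel_channels_equal_doubled_conductance(self):
        settings = net.SolverSettings(stop=0.05, tolerance=1e-11, interval=1e-3)
        g2 = _membrane(
            [_channel("a", 1e-9, -0.02), _channel("b", 1e-9, -0.02)],
            drive=quantity(-0.5e-9, "A"),
        )
        t2 = net.simulate(g2.assemble(), settings)
        g1 = _membrane(
            [_channel("a", 2e-9, -0.02)], drive=quantity(-0.5e-9, "A")
        )
        t1 = net.simulate(g1.assemble(), settings)
        np.testing.assert_allclose(
            t2["cm.v"], t1["cm.v"], rtol=0, atol=1e-10
        )

    def test_removing_a_channel_only_touches_its_node_term(self):
        g_full = _membrane([_channel("a"), _channel("b")], drive=0.0)
        g_less = _membrane([_channel("a")], drive=0.0)
        full = g_full.assemble().node_balances(0.0, g_full.assemble().y0)
        less = g_less.assemble().node_balances(0.0, g_less.assemble().y0)
        names_full = {n for n, _ in full["cm.n"]}
        names_less = {n for n, _ in less["cm.n"]}
        assert names_full - names_less == {"b"}

    def test_floating_subgraph_reported_with_component(self):
        g = net.ComponentGraph()
        ch = _channel("lonely")
        g.add(ch)
        with pytest.raises(net.AssemblyError) as err:
            g.assemble()
        assert "lonely" in str(err.value)

    def test_conflicting_potential_definers_rejected(self):
        g = net.ComponentGraph()
        gnd = net.Ground("gnd")
        cap = net.MembraneCapacitor("cm", quantity(1e-11, "F"))
        vc = net.VoltageSource("vc", drive=0.0)
        g.add(gnd, cap, vc)
        g.connect(gnd.pins["p"], cap.pins["p"])
        g.connect(gnd.pins["p"], vc.pins["p"])
        g.connect(cap.pins["n"], vc.pins["n"])
        with pytest.raises(net.AssemblyError):
            g.assemble()

    def test_state_ordering_is_lexicographic(self):
        g = build_demo_cell("N")
        sys = g.assemble()
        assert sys.state_names == sorted(sys.state_names)


class TestKirchhoff:
    @pytest.mark.parametrize("cell_type", ["AN", "N"])
    def test_node_balances_sum_to_zero_at_every_sample(self, cell_type):
        g = build_demo_cell(cell_type)
        sys = g.assemble()
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=0.35, tolerance=1e-8, atol=1e-28, interval=5e-3
            ),
        )
        arr = traj.data[sys.state_names].to_numpy()
        for t, row in zip(traj.time, arr):
            for node, terms in sys.node_balances(t, row).items():
                total = sum(v for _, v in terms)
                largest = max((abs(v) for _, v in terms), default=0.0)
                assert abs(total) <= 1e-12 * max(largest, 1e-300)

    def test_gates_remain_in_unit_interval(self):
        g = build_demo_cell("N")
        sys = g.assemble()
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=0.35, tolerance=1e-8, atol=1e-28, interval=5e-3
            ),
        )
        for name in sys.state_names:
            if name.endswith(".n") and "ca." not in name:
                vals = traj[name]
                assert np.all(vals >= -1e-9) and np.all(vals <= 1 + 1e-9)


class TestAcausality:
    def test_voltage_clamp_and_current_replay_agree(self):
        """The same channel gives the same current trace when driven by a
        voltage clamp and when a current clamp replays the clamp current."""
        settings = net.SolverSettings(stop=0.1, tolerance=1e-11, interval=5e-4)
        vhold = -0.01
        g_vc = net.ComponentGraph()
        chan = _channel("ch", with_gate=True)
        vc = net.VoltageSource("vc", drive=quantity(vhold, "V"))
        gnd = net.Ground("gnd")
        g_vc.add(chan, vc, gnd)
        g_vc.connect(gnd.pins["p"], vc.pins["p"])
        g_vc.connect(vc.pins["p"], chan.pins["p"])
        g_vc.connect(vc.pins["n"], chan.pins["n"])
        traj_vc = net.simulate(g_vc.assemble(), settings)
        i_ch = traj_vc["ch.i"]
        t = traj_vc.time

        replay = lambda tt: float(np.interp(tt, t, i_ch))
        chan2 = _channel("ch", with_gate=True)
        g_cc = _membrane([chan2], drive=replay, v0=vhold, c_m=4e-11)
        traj_cc = net.simulate(g_cc.assemble(), settings)
        np.testing.assert_allclose(
            traj_cc["ch.i"], i_ch, rtol=0, atol=1e-4 * np.abs(i_ch).max()
        )
        # the membrane potential stays pinned at the clamp level
        np.testing.assert_allclose(
            traj_cc["cm.v"], vhold, rtol=0, atol=1e-6
        )


class TestSimulate:
    def test_defaults_follow_published_experiment_annotation(self):
        s = net.SolverSettings()
        assert (s.start, s.stop, s.tolerance, s.interval) == (
            0.0,
            2.5,
            1e-12,
            1e-4,
        )

    def test_gate_relaxation_matches_closed_form(self):
        g = build_gate_relaxation()
        sys = g.assemble()
        gate = g.components["ch"].channel.gates["gate"]
        v = g.components["vc"].drive.si
        n_inf, tau = gate.fsteady(v), gate.ftau(v)
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=5 * tau, tolerance=1e-10, interval=tau / 20
            ),
        )
        exact = n_inf + (gate.n - n_inf) * np.exp(-traj.time / tau)
        assert np.max(np.abs(traj["ch.gate.n"] - exact)) < 1e-6

    def test_tolerance_refinement_converges(self):
        g = _membrane([_channel("a", with_gate=True)], drive=quantity(-0.2e-9, "A"))
        sys = g.assemble()
        coarse = net.simulate(
            sys, net.SolverSettings(stop=0.1, tolerance=1e-6, interval=1e-2)
        )
        fine = net.simulate(
            sys, net.SolverSettings(stop=0.1, tolerance=1e-12, interval=1e-2)
        )
        diff = abs(coarse["cm.v"][-1] - fine["cm.v"][-1])
        assert diff < 10 * 1e-6 * max(1.0, abs(fine["cm.v"][-1]))

    def test_failure_carries_time(self):
        blow_up = GateTS("g", lambda v: 1.0, lambda v: 1e-300, n=0.0)
        ch = net.ChannelComponent(
            "ch",
            ElectricChannel(
                "ch", quantity(1e-9, "S"), quantity(0.0, "V"), gates={"g": blow_up}
            ),
        )
        g = _membrane([ch], drive=0.0)
        sys = g.assemble()
        with pytest.raises((net.IntegrationError, ValueError, OverflowError)):
            net.simulate(
                sys, net.SolverSettings(stop=0.1, tolerance=1e-10, interval=1e-3)
            )


class TestInitializeSteady:
    def test_gate_relaxes_to_steady_state(self):
        g = build_gate_relaxation()
        sys = g.assemble()
        gate = g.components["ch"].channel.gates["gate"]
        v = g.components["vc"].drive.si
        tau = gate.ftau(v)
        # e^-20 of the initial offset leaves the gate within 1e-6 of n_inf
        res = net.initialize_steady(sys, 20 * tau)
        assert res.converged
        idx = sys.state_index("ch.gate.n")
        assert res.state[idx] == pytest.approx(gate.fsteady(v), abs=1e-6)

    def test_steady_state_is_a_fixed_point(self):
        g = build_gate_relaxation()
        sys = g.assemble()
        gate = g.components["ch"].channel.gates["gate"]
        tau = gate.ftau(g.components["vc"].drive.si)
        first = net.initialize_steady(sys, 20 * tau)
        again = net.initialize_steady(sys, 20 * tau, y0=first.state)
        np.testing.assert_allclose(again.state, first.state, atol=1e-9)

    def test_unrelaxed_system_flagged(self):
        g = build_gate_relaxation()
        sys = g.assemble()
        gate = g.components["ch"].channel.gates["gate"]
        tau = gate.ftau(g.components["vc"].drive.si)
        res = net.initialize_steady(sys, tau / 10, tolerance=1e-9)
        assert not res.converged

    def test_nonpositive_relaxation_time_rejected(self):
        g = build_gate_relaxation()
        sys = g.assemble()
        with pytest.raises(ValueError):
            net.initialize_steady(sys, 0.0)


class TestUnitAudit:
    def test_all_shipped_presets_pass(self):
        from avnode.presets import MODELS

        for name, builder in MODELS.items():
            g = builder()
            g.assemble()
            verdicts = audit_model_units(g)
            assert verdicts and all(v.passed for v in verdicts), name

    def test_mis_united_conductance_flagged(self):
        ch = _channel("bad")
        ch.channel.g_max = quantity(1.0, "V")  # wrong on purpose
        g = _membrane([ch], drive=0.0)
        g.assemble()
        verdicts = audit_model_units(g)
        assert any(not v.passed for v in verdicts)
        assert any("bad" in v.context for v in verdicts if not v.passed)

    def test_unassembled_graph_rejected(self):
        g = build_gate_relaxation()
        with pytest.raises(net.AssemblyError):
            audit_model_units(g)
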