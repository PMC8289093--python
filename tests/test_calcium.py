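"""Calcium compartments, buffers, transport, and closed-system conservation."""

import numpy as np
import pytest

from avnode import network as net
from avnode.calcium import (
    BufferSpec,
    CompartmentSpec,
    GaussianStimulus,
    TransportSpec,
    buffer_rhs,
    current_to_molar_flow,
    gaussian_stimulus,
    transport_flow,
)
from avnode.channels import FARADAY
from avnode.presets import build_calcium_subsystem
from avnode.quantities import quantity


def _buffer(kf=534.0, kb=446.0, ct=0.031) -> BufferSpec:
    return BufferSpec(
        "TC",
        quantity(ct, "mM"),
        quantity(kf, "1/(mM.s)"),
        quantity(kb, "1/s"),
    )


class TestBufferKinetics:
    def test_empty_buffer_without_calcium_is_inert(self):
        assert buffer_rhs(_buffer(), 0.0, 0.0).si == 0.0

    def test_half_occupancy_steady_state_when_kb_equals_kf_c(self):
        c = 0.5  # mM
        b = _buffer(kf=100.0, kb=100.0 * c)
        f_star = 0.5
        assert buffer_rhs(b, f_star, quantity(c, "mM")).si == pytest.approx(0.0)

    def test_troponin_on_rate_magnitude(self, registry):
        # corrected troponin on-rate, 1 mM calcium, empty buffer
        kf = registry.lookup("kfTC")
        b = _buffer(kf=kf.si)
        assert buffer_rhs(b, 0.0, quantity(1.0, "mM")).si == pytest.approx(534.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BufferSpec(
                "x",
                quantity(1.0, "mM"),
                quantity(-1.0, "1/(mM.s)"),
                quantity(1.0, "1/s"),
            )


class TestTransportFlow:
    def test_no_gradient_no_flow(self):
        t = TransportSpec("tr", "nsr", "jsr", quantity(10.0, "1/s"))
        v = quantity(1e-15, "m^3")
        assert transport_flow(t, v, v, 1.0, 1.0).si == 0.0

    def test_equal_volumes_reduce_to_simplified_printed_form(self):
        """With V_src = V_dst = V the destination's concentration rate is
        P*(c_src - c_dst): the volume factors cancel."""
        P = 7.0
        V = 2e-15
        t = TransportSpec("rel", "jsr", "sub", quantity(P, "1/s"))
        phi = transport_flow(
            t, quantity(V, "m^3"), quantity(V, "m^3"), 0.9, 0.2
        )
        dc_dst = phi.si / V
        assert dc_dst == pytest.approx(P * (0.9 - 0.2), rel=1e-12)

    def test_min_volume_rule(self):
        t = TransportSpec("up", "cyto", "nsr", quantity(3.0, "1/s"))
        phi = transport_flow(
            t, quantity(4e-15, "m^3"), quantity(1e-15, "m^3"), 1.0, 0.0
        )
        assert phi.si == pytest.approx(3.0 * 1e-15)

    def test_amount_conservation_by_construction(self):
        t = TransportSpec("diff", "sub", "cyto", quantity(25.0, "1/s"))
        phi = transport_flow(
            t, quantity(1e-17, "m^3"), quantity(2e-15, "m^3"), 0.7, 0.1
        )
        dn_src, dn_dst = -phi.si, +phi.si
        assert dn_src + dn_dst == 0.0


class TestCurrentCoupling:
    def test_zero_current_zero_flow(self):
        assert current_to_molar_flow(0.0, 2).si == 0.0

    def test_definition(self):
        i = quantity(2.0 * FARADAY, "A")
        assert current_to_molar_flow(i, 2).si == pytest.approx(-1.0)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            current_to_molar_flow(1.0, 0)

    def test_charge_balance_over_closed_loop(self):
        """Integrating a current into a compartment moves exactly
        z*F*(Delta n) of charge."""
        stim = GaussianStimulus(
            [(quantity(-0.1e-9, "A"), quantity(0.05, "s"), quantity(0.01, "s"))]
        )
        g = net.ComponentGraph()
        comp = net.CompartmentComponent(
            "sub",
            CompartmentSpec(
                "sub", quantity(4.4e-17, "m^3"), quantity(0.0002, "mM")
            ),
        )
        src = net.ChemicalCurrentSource("ical", drive=stim.current_si, z=2)
        g.add(comp, src)
        g.connect(src.ports["ca"], comp.ports["ca"])
        sys = g.assemble()
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=0.2, tolerance=1e-10, atol=1e-30, interval=1e-3
            ),
        )
        dn = traj["sub.n"][-1] - traj["sub.n"][0]
        t_dense = np.linspace(0.0, 0.2, 20001)
        charge = np.trapezoid([stim.current_si(t) for t in t_dense], t_dense)
        assert 2 * FARADAY * dn == pytest.approx(-charge, rel=1e-6)


class TestGaussianStimulus:
    def test_peak_value(self):
        s = GaussianStimulus(
            [(quantity(-0.2e-9, "A"), quantity(0.02, "s"), quantity(0.004, "s"))]
        )
        assert gaussian_stimulus(s, quantity(0.02, "s")).si == pytest.approx(-0.2e-9)

    def test_far_tail_is_negligible(self):
        s = GaussianStimulus(
            [(quantity(1.0, "A"), quantity(0.0, "s"), quantity(0.01, "s"))]
        )
        assert abs(gaussian_stimulus(s, 0.1).si) < 2e-22

    def test_components_superpose(self):
        a = (quantity(1.0, "A"), quantity(0.0, "s"), quantity(0.01, "s"))
        b = (quantity(-0.5, "A"), quantity(0.02, "s"), quantity(0.005, "s"))
        s_ab = GaussianStimulus([a, b])
        s_a, s_b = GaussianStimulus([a]), GaussianStimulus([b])
        t = 0.013
        assert s_ab.current_si(t) == pytest.approx(
            s_a.current_si(t) + s_b.current_si(t)
        )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            GaussianStimulus(
                [(quantity(1.0, "A"), quantity(0.0, "s"), quantity(0.0, "s"))]
            )


def _total_calcium(g, sys, row) -> float:
    total = 0.0
    for comp in g.components.values():
        if isinstance(comp, net.CompartmentComponent):
            total += row[sys.state_index(f"{comp.name}.n")]
        elif isinstance(comp, net.BufferComponent):
            node = sys._node_of[comp.ports["ca"]]
            host = sys._conc_def[node][1]
            total += (
                comp.spec.total.si
                * host.spec.volume.si
                * row[sys.state_index(f"{comp.name}.f")]
            )
    return total


class TestClosedSystem:
    def test_total_calcium_conserved_over_ten_seconds(self):
        """Compartments + buffers + all transport, no external currents:
        free plus buffer-bound calcium is a constant of motion."""
        g = build_calcium_subsystem(stimulus=False)
        sys = g.assemble()
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=10.0, tolerance=1e-10, atol=1e-30, interval=0.05
            ),
        )
        arr = traj.data[sys.state_names].to_numpy()
        totals = np.array([_total_calcium(g, sys, r) for r in arr])
        drift = np.max(np.abs(totals - totals[0])) / totals[0]
        assert drift < 1e-9

    def test_occupancies_and_concentrations_stay_physical(self):
        g = build_calcium_subsystem(stimulus=True)
        sys = g.assemble()
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=0.3, tolerance=1e-10, atol=1e-28, interval=1e-3
            ),
        )
        for name in sys.state_names:
            vals = traj[name]
            if name.endswith(".f"):
                assert np.all(vals >= -1e-9) and np.all(vals <= 1 + 1e-9)
            if name.endswith(".n"):
                assert np.all(vals >= -1e-20)

    def test_passive_transport_equilibrates_concentrations(self):
        """With positive rates everywhere and no pump/buffers/sources, all
        compartments relax to one common concentration."""
        g = build_calcium_subsystem(
            include_serca=False, include_buffers=False, stimulus=False
        )
        sys = g.assemble()
        # slowest relaxation rate of a compartment is P*min(V)/V_side
        vols = {
            c.name.split(".")[-1]: c.spec.volume.si
            for c in g.components.values()
            if isinstance(c, net.CompartmentComponent)
        }
        eff_rates = []
        for c in g.components.values():
            if isinstance(c, net.TransportComponent):
                vs, vd = vols[c.spec.src], vols[c.spec.dst]
                vmin = min(vs, vd)
                eff_rates += [c.spec.rate.si * vmin / vs, c.spec.rate.si * vmin / vd]
        horizon = 30.0 / min(eff_rates)
        traj = net.simulate(
            sys,
            net.SolverSettings(
                stop=horizon,
                tolerance=1e-10,
                atol=1e-30,
                interval=horizon / 100,
            ),
        )
        final = {
            c.name: traj[f"{c.name}.c"][-1]
            for c in g.components.values()
            if isinstance(c, net.CompartmentComponent)
        }
        spread = max(final.values()) - min(final.values())
        assert spread < 1e-6  # mM
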