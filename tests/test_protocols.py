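"""Test-pulse / current-pulse drives and I-V curve extraction."""

import numpy as np
import pytest

from avnode import network as net
from avnode.channels import ElectricChannel
from avnode.kinetics import GateTS, GenLogisticParams
from avnode.presets import build_ist_voltage_clamp
from avnode.protocols import (
    CurrentPulseProtocol,
    IVCurve,
    TestPulseProtocol,
    extract_peak,
    protocol_drive,
    run_iv,
)
from avnode.quantities import quantity

mV = lambda x: quantity(x * 1e-3, "V")


def _test_pulse(sweep=(-40.0, -20.0, 0.0), t_hold=0.02, t_pulse=0.01):
    return TestPulseProtocol(
        v_hold=mV(-70.0),
        sweep=[mV(v) for v in sweep],
        t_hold=quantity(t_hold, "s"),
        t_pulse=quantity(t_pulse, "s"),
    )


class TestDrives:
    def test_holding_level_at_time_zero(self):
        p = _test_pulse()
        assert protocol_drive(p, 0.0).si == pytest.approx(-70e-3)

    def test_pulse_level_inside_pulse_window(self):
        p = _test_pulse()
        p.active = mV(-20.0)
        assert protocol_drive(p, 0.0201).si == pytest.approx(-20e-3)

    def test_current_protocol_with_published_settings(self):
        # T_hold = 300 ms, T_pulse = 1 ms, I_pulse = -1.2 nA
        p = CurrentPulseProtocol(
            t_hold=quantity(0.3, "s"),
            t_pulse=quantity(1e-3, "s"),
            i_pulse=quantity(-1.2e-9, "A"),
        )
        assert protocol_drive(p, 0.15).si == 0.0
        assert protocol_drive(p, 0.3005).si == pytest.approx(-1.2e-9)
        assert protocol_drive(p, 0.302).si == 0.0

    @pytest.mark.parametrize("t", [0.0, 0.013, 0.02, 0.0299, 0.1234])
    def test_exact_periodicity(self, t):
        p = _test_pulse()
        period = p.t_hold.si + p.t_pulse.si
        assert p.value_si(t) == p.value_si(t + period)
        cp = CurrentPulseProtocol(
            quantity(0.3, "s"), quantity(1e-3, "s"), quantity(-1.2e-9, "A")
        )
        assert cp.value_si(t) == cp.value_si(t + cp.period)

    def test_discontinuities_cover_pulse_edges(self):
        p = _test_pulse(t_hold=0.02, t_pulse=0.01)
        edges = p.discontinuities(0.0, 0.07)
        assert edges == pytest.approx([0.02, 0.03, 0.05, 0.06])

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            TestPulseProtocol(
                mV(-70), [], quantity(0.1, "s"), quantity(0.1, "s")
            )
        with pytest.raises(ValueError):
            CurrentPulseProtocol(
                quantity(1e-3, "s"), quantity(0.3, "s"), quantity(-1e-9, "A")
            )


class TestExtractPeak:
    def _traj(self, values):
        import pandas as pd

        t = np.linspace(0.0, 1.0, len(values))
        return net.Trajectory(pd.DataFrame({"time": t, "i": values}))

    def test_constant_trace(self):
        traj = self._traj([3e-9] * 11)
        assert extract_peak(traj, "i", (0.0, 1.0)).si == pytest.approx(3e-9)

    def test_signed_value_of_largest_magnitude(self):
        traj = self._traj([0, -5e-9, 3e-9, 0])
        assert extract_peak(traj, "i", (0.0, 1.0)).si == pytest.approx(-5e-9)

    def test_max_and_min_modes(self):
        traj = self._traj([0, -5e-9, 3e-9, 0])
        assert extract_peak(traj, "i", (0, 1), "max").si == pytest.approx(3e-9)
        assert extract_peak(traj, "i", (0, 1), "min").si == pytest.approx(-5e-9)

    def test_monotone_relaxation_peaks_at_endpoint(self):
        vals = 1e-9 * (1 - np.exp(-np.linspace(0, 5, 50)))
        traj = self._traj(vals)
        assert extract_peak(traj, "i", (0.0, 1.0)).si == pytest.approx(vals[-1])

    def test_empty_window_rejected(self):
        traj = self._traj([1e-9, 2e-9])
        with pytest.raises(ValueError):
            extract_peak(traj, "i", (0.5, 0.5))


class TestIVCurve:
    def test_potentials_must_strictly_increase(self):
        with pytest.raises(ValueError):
            IVCurve((0.0, 0.0), (1.0, 2.0))


def _clamped(channel_component):
    g = net.ComponentGraph()
    vc = net.VoltageSource("vc", drive=0.0)
    gnd = net.Ground("gnd")
    g.add(channel_component, vc, gnd)
    g.connect(gnd.pins["p"], vc.pins["p"])
    g.connect(vc.pins["p"], channel_component.pins["p"])
    g.connect(vc.pins["n"], channel_component.pins["n"])
    return g


class TestRunIV:
    def test_linear_conductor_gives_exact_ohmic_curve(self):
        g_max = 2e-9
        ch = net.ChannelComponent(
            "r",
            ElectricChannel("r", quantity(g_max, "S"), quantity(0.0, "V")),
        )
        g = _clamped(ch)
        p = _test_pulse(sweep=(-40.0, -20.0, 0.0, 20.0), t_hold=5e-3, t_pulse=5e-3)
        g.components["vc"].drive = p
        curve = run_iv(g, p, "r.i", interval=1e-3)
        v, i = curve.as_arrays()
        np.testing.assert_allclose(i, g_max * v, rtol=1e-9, atol=1e-30)

    def test_fixed_open_channel_slope_and_zero_crossing(self):
        v_eq = -37.4e-3
        ch = net.ChannelComponent(
            "ist",
            ElectricChannel("ist", quantity(0.1e-9, "S"), quantity(v_eq, "V")),
        )
        g = _clamped(ch)
        p = _test_pulse(sweep=np.arange(-60.0, 1.0, 10.0), t_hold=5e-3, t_pulse=5e-3)
        g.components["vc"].drive = p
        v, i = run_iv(g, p, "ist.i", interval=1e-3).as_arrays()
        slope = np.polyfit(v, i, 1)[0]
        assert slope == pytest.approx(0.1e-9, rel=1e-6)
        zero_crossing = v[np.argmin(np.abs(i))]
        assert zero_crossing == pytest.approx(-40e-3, abs=5e-3)  # grid point nearest v_eq

    def test_memoryless_channel_invariant_to_holding_time(self):
        ch = net.ChannelComponent(
            "r", ElectricChannel("r", quantity(1e-9, "S"), quantity(0.0, "V"))
        )
        g = _clamped(ch)
        p_short = _test_pulse(t_hold=1e-3, t_pulse=5e-3)
        g.components["vc"].drive = p_short
        short = run_iv(g, p_short, "r.i", interval=1e-3)
        p_long = _test_pulse(t_hold=0.1, t_pulse=5e-3)
        g.components["vc"].drive = p_long
        long = run_iv(g, p_long, "r.i", interval=1e-3)
        np.testing.assert_allclose(
            short.as_arrays()[1], long.as_arrays()[1], rtol=1e-9
        )

    def test_short_holding_time_distorts_gated_channel_curve(self):
        """With T_hold far below the slowest gate time constant the gates
        cannot recover between cycles and the extracted curve changes."""
        sweep = (-60.0, -40.0, -20.0, 0.0)

        def fresh(p):
            g = build_ist_voltage_clamp()
            g.components["vc"].drive = p
            return g

        taus = [0.5]  # slowest synthetic inactivation ceiling, seconds
        p_long = TestPulseProtocol(
            mV(-70), [mV(v) for v in sweep],
            t_hold=quantity(20 * max(taus), "s"),
            t_pulse=quantity(0.2, "s"),
        )
        long = run_iv(fresh(p_long), p_long, "ist.i", interval=2e-3)
        p_short = TestPulseProtocol(
            mV(-70), [mV(v) for v in sweep],
            t_hold=quantity(max(taus) / 10, "s"),
            t_pulse=quantity(0.2, "s"),
        )
        short = run_iv(
            fresh(p_short), p_short, "ist.i", interval=2e-3, mode="sequential"
        )
        delta = np.abs(long.as_arrays()[1] - short.as_arrays()[1])
        assert delta.max() > 0.0

    def test_missing_clamp_reported(self):
        from avnode.protocols import ProtocolError

        g = _clamped(
            net.ChannelComponent(
                "r", ElectricChannel("r", quantity(1e-9, "S"), quantity(0, "V"))
            )
        )
        p = _test_pulse()
        with pytest.raises(ProtocolError):
            run_iv(g, p, "r.i")  # clamp drive never bound to p
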