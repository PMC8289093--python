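"""Shipped demo components and model presets.

The published AV-node cell family prints only a handful of component
parameterizations (the sustained-inward channel constants, the sodium
fast/slow inactivation time-constant fits, the registry values in
``data/registry.yaml``).  Everything else needed to exercise the kit —
steady-state fits, activation rates, buffer and transport parameters —
is a SYNTHETIC placeholder chosen for physiological plausibility and
numerical good behavior, and is labeled as such here.  The presets are
demonstration and regression fixtures, not reference reproductions.

Model presets are registered in :data:`MODELS` and addressed by name from
experiment configs (``model: sodium_iv`` etc.).
"""

from __future__ import annotations

import math
from typing import Callable

from . import calcium as ca
from . import network as net
from .channels import ElectricChannel, GHKChannel, OpenRatioExpr
from .kinetics import GateAB, GateTS, GenLogisticParams
from .protocols import CurrentPulseProtocol, TestPulseProtocol
from .quantities import quantity
from .registry import load_registry

__all__ = [
    "sodium_inact_fast_tau",
    "sodium_inact_slow_tau",
    "sodium_channel",
    "sustained_inward_channel",
    "background_channel",
    "demo_exchanger_rates",
    "build_gate_relaxation",
    "build_sodium_voltage_clamp",
    "build_ist_voltage_clamp",
    "build_calcium_subsystem",
    "build_demo_cell",
    "MODELS",
]


def sodium_inact_fast_tau() -> GenLogisticParams:
    """Printed time-constant fit of the sodium fast-inactivation gate.

    Declining sigmoid with asymptotes 0.35 ms / 30.35 ms and maximal
    steepness at -40 mV.
    """
    return GenLogisticParams.in_si(
        y_min=0.00035, y_max=0.03 + 0.00035, x0=-0.040, sx=-1000.0 / 6.0
    )


def sodium_inact_slow_tau() -> GenLogisticParams:
    """Printed time-constant fit of the sodium slow-inactivation gate."""
    return GenLogisticParams.in_si(
        y_min=0.00295, y_max=0.12 + 0.00295, x0=-0.060, sx=-1000.0 / 2.0
    )


def _inact_steady() -> GenLogisticParams:
    """SYNTHETIC inactivation steady state (declining sigmoid near -66 mV)."""
    return GenLogisticParams.in_si(
        y_min=0.0, y_max=1.0, x0=-0.066, sx=-1000.0 / 6.4, y_unit="1"
    )


def _logistic_rate(r_max: float, x0: float, sx: float) -> Callable[[float], float]:
    def rate(v: float) -> float:
        u = max(-700.0, min(700.0, sx * (v - x0)))
        return r_max / (1.0 + math.exp(-u))

    return rate


def _sodium_act_gate(v0: float = -0.080) -> GateAB:
    """SYNTHETIC sodium activation gate in alpha/beta form (~0.1 ms tau)."""
    alpha = _logistic_rate(8000.0, -0.035, 150.0)
    beta = _logistic_rate(8000.0, -0.045, -150.0)
    n0 = alpha(v0) / (alpha(v0) + beta(v0))
    return GateAB("act", alpha, beta, n=n0)


def sodium_channel(v0: float = -0.080) -> GHKChannel:
    """Demo sodium channel: GHK flux with the printed open-ratio algebra.

    The inactivation time-constant fits are the printed ones; the
    activation rates, steady-state fits, permeability-area product and
    concentrations are SYNTHETIC placeholders.
    """
    steady = _inact_steady()
    fast = GateTS.from_logistic("inact_fast", steady, sodium_inact_fast_tau())
    slow = GateTS.from_logistic("inact_slow", steady, sodium_inact_slow_tau())
    fast.n = fast.fsteady(v0)
    slow.n = slow.fsteady(v0)
    return GHKChannel(
        name="na",
        p_area=quantity(2e-17, "m^3/s"),  # SYNTHETIC
        z=1,
        c_in=quantity(8.0, "mM"),  # SYNTHETIC intracellular Na
        c_out=quantity(140.0, "mM"),  # SYNTHETIC extracellular Na
        gates={
            "act": _sodium_act_gate(v0),
            "inact_fast": fast,
            "inact_slow": slow,
        },
        open_ratio=OpenRatioExpr(
            "act^3 * (0.635*inact_fast + 0.365*inact_slow)"
        ),
    )


def sustained_inward_channel(v0: float = -0.080) -> ElectricChannel:
    """The sustained inward channel: printed electric-analog constants
    (g_max = 0.1 nS, v_eq = -37.4 mV), SYNTHETIC gate fits."""
    act_steady = GenLogisticParams.in_si(
        0.0, 1.0, x0=-0.057, sx=1000.0 / 5.0, y_unit="1"
    )
    act_tau = GenLogisticParams.in_si(
        0.002, 0.01, x0=-0.050, sx=-1000.0 / 10.0
    )
    inact_steady = GenLogisticParams.in_si(
        0.0, 1.0, x0=-0.045, sx=-1000.0 / 8.0, y_unit="1"
    )
    inact_tau = GenLogisticParams.in_si(
        0.1, 0.5, x0=-0.060, sx=-1000.0 / 10.0
    )
    act = GateTS.from_logistic("act", act_steady, act_tau)
    inact = GateTS.from_logistic("inact", inact_steady, inact_tau)
    act.n = act.fsteady(v0)
    inact.n = inact.fsteady(v0)
    return ElectricChannel(
        name="ist",
        g_max=quantity(0.1e-9, "S"),
        v_eq=quantity(-37.4e-3, "V"),
        gates={"act": act, "inact": inact},
        open_ratio=OpenRatioExpr("act * inact"),
    )


def background_channel() -> ElectricChannel:
    """SYNTHETIC linear background conductance (gateless)."""
    return ElectricChannel(
        name="bg",
        g_max=quantity(1.0e-9, "S"),
        v_eq=quantity(-40e-3, "V"),
    )


def demo_exchanger_rates():
    """SYNTHETIC constant 4-state rates (detailed balance broken on purpose
    so the exchanger carries a nonzero steady current)."""
    from .exchanger import FourStateRates

    return FourStateRates(
        k12=0.04, k21=0.08, k23=0.5, k32=0.1,
        k34=1.0, k43=0.5, k14=0.03, k41=0.7,
    )


# ---------------------------------------------------------------------------
# model presets
# ---------------------------------------------------------------------------

def _demo_gate(v0: float = -0.020) -> GateTS:
    """A single SYNTHETIC demonstration gate (ms-scale kinetics)."""
    steady = GenLogisticParams.in_si(
        0.0, 1.0, x0=-0.030, sx=1000.0 / 8.0, y_unit="1"
    )
    tau = GenLogisticParams.in_si(0.005, 0.03, x0=-0.040, sx=-1000.0 / 10.0)
    gate = GateTS.from_logistic("gate", steady, tau)
    gate.n = 0.0
    return gate


def build_gate_relaxation() -> net.ComponentGraph:
    """A single HH gate relaxing under a constant -20 mV clamp."""
    g = net.ComponentGraph()
    ch = ElectricChannel(
        name="ch",
        g_max=quantity(1e-9, "S"),
        v_eq=quantity(0.0, "V"),
        gates={"gate": _demo_gate()},
    )
    chan = net.ChannelComponent("ch", ch)
    clamp = net.VoltageSource("vc", drive=quantity(-20e-3, "V"))
    gnd = net.Ground("gnd")
    g.add(chan, clamp, gnd)
    g.connect(gnd.pins["p"], clamp.pins["p"])
    g.connect(clamp.pins["p"], chan.pins["p"])
    g.connect(clamp.pins["n"], chan.pins["n"])
    return g


def _voltage_clamp_graph(channel_component: net.Component) -> net.ComponentGraph:
    g = net.ComponentGraph()
    clamp = net.VoltageSource("vc", drive=quantity(-80e-3, "V"))
    gnd = net.Ground("gnd")
    g.add(channel_component, clamp, gnd)
    g.connect(gnd.pins["p"], clamp.pins["p"])
    g.connect(clamp.pins["p"], channel_component.pins["p"])
    g.connect(clamp.pins["n"], channel_component.pins["n"])
    return g


def build_sodium_voltage_clamp() -> net.ComponentGraph:
    """Sodium channel in isolation under a voltage clamp (I-V unit test)."""
    return _voltage_clamp_graph(net.GHKComponent("na", sodium_channel()))


def build_ist_voltage_clamp() -> net.ComponentGraph:
    """Sustained-inward channel in isolation under a voltage clamp."""
    return _voltage_clamp_graph(
        net.ChannelComponent("ist", sustained_inward_channel())
    )


def build_calcium_subsystem(
    cell_type: str = "AN",
    include_serca: bool = True,
    include_buffers: bool = True,
    stimulus: bool = False,
    prefix: str = "ca",
    graph: net.ComponentGraph | None = None,
) -> net.ComponentGraph:
    """The four-compartment calcium subsystem.

    Volumes use the C++ cell volume from the registry with SYNTHETIC
    sub-volume fractions; release rates are the registry's corrected
    values; diffusion/transfer rates, SERCA and buffer parameters are
    SYNTHETIC.  With ``stimulus=True``, sum-of-Gaussians dummy currents
    stand in for the calcium-carrying membrane currents so the subsystem
    runs in isolation.
    """
    reg = load_registry()
    g = graph if graph is not None else net.ComponentGraph()
    v_cell = reg.lookup("V_cell", cell_type, "cpp").si
    fractions = {  # SYNTHETIC partition of the cell volume
        "cyto": 0.46,
        "sub": 0.01,
        "jsr": 0.0012,
        "nsr": 0.0116,
    }
    c0 = {  # SYNTHETIC initial concentrations, mM
        "cyto": 0.0002,
        "sub": 0.0002,
        "jsr": 0.4,
        "nsr": 1.1,
    }
    comps: dict[str, net.CompartmentComponent] = {}
    for name in ca.COMPARTMENT_NAMES:
        spec = ca.CompartmentSpec(
            name,
            quantity(fractions[name] * v_cell, "m^3"),
            quantity(c0[name], "mM"),
        )
        comp = net.CompartmentComponent(f"{prefix}.{name}", spec)
        comps[name] = comp
        g.add(comp)

    p_rel = reg.lookup("P_rel", cell_type, "corrected")
    links = [
        ("rel", "jsr", "sub", p_rel),
        ("diff", "sub", "cyto", quantity(25000.0, "1/s")),  # SYNTHETIC
        ("tr", "nsr", "jsr", quantity(16.7, "1/s")),  # SYNTHETIC
    ]
    for label, src, dst, rate in links:
        t = net.TransportComponent(
            f"{prefix}.{label}", ca.TransportSpec(label, src, dst, rate)
        )
        g.add(t)
        g.connect(t.ports["src"], comps[src].ports["ca"])
        g.connect(t.ports["dst"], comps[dst].ports["ca"])
    if include_serca:
        serca = net.ActiveTransportComponent(
            f"{prefix}.up",
            v_max=quantity(1e-14, "mol/s"),  # SYNTHETIC
            k_m=quantity(0.0006, "mM"),  # SYNTHETIC
        )
        g.add(serca)
        g.connect(serca.ports["src"], comps["cyto"].ports["ca"])
        g.connect(serca.ports["dst"], comps["nsr"].ports["ca"])
    if include_buffers:
        buffers = [
            # (name, host, CT mM, kf 1/(mM.s), kb 1/s); kf of TC is the
            # registry's corrected value, everything else SYNTHETIC
            ("TC", "cyto", 0.031, reg.lookup("kfTC").value, 446.0),
            ("CM", "sub", 0.045, 120000.0, 542.0),
            ("CQ", "jsr", 10.0, 480.0, 400.0),
        ]
        for bname, host, ct, kf, kb in buffers:
            spec = ca.BufferSpec(
                bname,
                quantity(ct, "mM"),
                quantity(kf, "1/(mM.s)"),
                quantity(kb, "1/s"),
                f0=0.1,
            )
            buf = net.BufferComponent(f"{prefix}.{bname}", spec)
            g.add(buf)
            g.connect(buf.ports["ca"], comps[host].ports["ca"])
    if stimulus:
        # dummy membrane currents: inward Ca-carrying pulse shapes
        ical = ca.GaussianStimulus(
            [
                (
                    quantity(-0.2e-9, "A"),
                    quantity(0.02, "s"),
                    quantity(0.004, "s"),
                ),
                (
                    quantity(-0.05e-9, "A"),
                    quantity(0.05, "s"),
                    quantity(0.02, "s"),
                ),
            ]
        )
        inaca = ca.GaussianStimulus(
            [
                (
                    quantity(0.04e-9, "A"),
                    quantity(0.06, "s"),
                    quantity(0.03, "s"),
                )
            ]
        )
        for sname, stim in (("ical_dummy", ical), ("inaca_dummy", inaca)):
            src = net.ChemicalCurrentSource(
                f"{prefix}.{sname}", drive=stim.current_si, z=2
            )
            g.add(src)
            g.connect(src.ports["ca"], comps["sub"].ports["ca"])
    return g


def build_calcium_dummy() -> net.ComponentGraph:
    """Calcium handling in isolation, driven by dummy Gaussian currents."""
    return build_calcium_subsystem(stimulus=True)


def build_demo_cell(cell_type: str = "AN") -> net.ComponentGraph:
    """A reduced demonstration cell under a current-pulse protocol.

    Membrane capacitance and pulse settings are the published ones
    (C_m from the registry; T_hold = 300 ms, T_pulse = 1 ms,
    I_pulse = -1.2 nA); the channel complement is the reduced demo set
    (background + sodium + sustained inward for the N cell), not the full
    published cell, plus the calcium subsystem driven by dummy currents.
    """
    reg = load_registry()
    g = net.ComponentGraph()
    gnd = net.Ground("gnd")
    cap = net.MembraneCapacitor(
        "cell.cm",
        reg.lookup("C_m", cell_type, "corrected"),
        v0=quantity(-60e-3, "V"),
    )
    pulse = CurrentPulseProtocol(
        t_hold=quantity(0.3, "s"),
        t_pulse=quantity(1e-3, "s"),
        i_pulse=quantity(-1.2e-9, "A"),
    )
    stim = net.CurrentSource("cell.stim", drive=pulse)
    bg = net.ChannelComponent("cell.bg", background_channel())
    na = net.GHKComponent("cell.na", sodium_channel(v0=-0.060))
    members: list[net.Component] = [gnd, cap, stim, bg, na]
    if cell_type == "N":
        members.append(
            net.ChannelComponent(
                "cell.ist", sustained_inward_channel(v0=-0.060)
            )
        )
    g.add(*members)
    outside = gnd.pins["p"]
    for comp in members[1:]:
        g.connect(outside, comp.pins["p"])
    inside = cap.pins["n"]
    for comp in members[2:]:
        g.connect(inside, comp.pins["n"])
    build_calcium_subsystem(
        cell_type=cell_type, stimulus=True, prefix="cell.ca", graph=g
    )
    return g


#: Named model presets addressable from experiment configs.
MODELS: dict[str, Callable[[], net.ComponentGraph]] = {
    "gate_relaxation": build_gate_relaxation,
    "sodium_voltage_clamp": build_sodium_voltage_clamp,
    "ist_voltage_clamp": build_ist_voltage_clamp,
    "calcium_dummy": build_calcium_dummy,
    "calcium_closed": lambda: build_calcium_subsystem(stimulus=False),
    "demo_cell_an": lambda: build_demo_cell("AN"),
    "demo_cell_n": lambda: build_demo_cell("N"),
}
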