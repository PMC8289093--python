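"""Voltage-clamp test-pulse and current-pulse experiment protocols.

A test-pulse protocol holds the membrane at V_hold for T_hold, steps to
V_pulse for T_pulse, and repeats; the peak current per cycle plotted
against the swept potential gives the channel's I-V curve.  Protocol
objects double as clamp drives for :mod:`avnode.network` sources (they
expose ``value_si`` and their step ``discontinuities``).

Two deliberate options where the published description is ambiguous:

* the swept variable defaults to the *pulse* potential (each experiment
  fixes its holding potential), but ``sweep_variable="hold"`` is
  supported;
* "maximum current" defaults to the signed extremum of largest magnitude
  inside the pulse window; ``peak_mode`` and an explicit window let users
  choose plain max/min or the whole cycle instead.

Because slow gates may need tens of seconds to reach their steady state,
each sweep value is by default re-initialized independently by relaxing
at the holding level for T_hold; ``mode="sequential"`` chains the cycles
instead, reproducing the incomplete-recovery artifact a too-short T_hold
causes in real protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (
    AssembledODE,
    ComponentGraph,
    SolverSettings,
    Trajectory,
    VoltageSource,
    initialize_steady,
    simulate,
)
from .quantities import Quantity, parse_unit, quantity

__all__ = [
    "TestPulseProtocol",
    "CurrentPulseProtocol",
    "IVCurve",
    "ProtocolError",
    "protocol_drive",
    "run_iv",
    "extract_peak",
]

_VOLT = parse_unit("V").signature
_AMPERE = parse_unit("A").signature
_TIME = parse_unit("s").signature


class ProtocolError(RuntimeError):
    """A protocol run failed; the message names the offending sweep value."""


def _si(x: Quantity | float, sig, what: str) -> float:
    if isinstance(x, Quantity):
        if x.signature != sig:
            raise ValueError(f"{what}: wrong unit signature {x.signature}")
        return x.si
    return float(x)


@dataclass
class TestPulseProtocol:
    """Repeated hold/pulse voltage-clamp cycles with a swept level.

    Cycle k covers [k*(T_hold+T_pulse), (k+1)*(T_hold+T_pulse)); the pulse
    occupies the final T_pulse of each cycle.  ``active`` is the sweep
    level currently applied by the drive (set per sweep by
    :func:`run_iv`).
    """

    __test__ = False  # domain class, not a pytest collection target

    v_hold: Quantity
    sweep: Sequence[Quantity]
    t_hold: Quantity
    t_pulse: Quantity
    sweep_variable: str = "pulse"
    v_pulse: Quantity | None = None  # fixed pulse level when sweeping hold

    def __post_init__(self) -> None:
        if self.t_hold.si <= 0 or self.t_pulse.si <= 0:
            raise ValueError("T_hold and T_pulse must be positive")
        if not self.sweep:
            raise ValueError("sweep must be nonempty")
        if self.sweep_variable not in ("pulse", "hold"):
            raise ValueError("sweep_variable must be 'pulse' or 'hold'")
        if self.sweep_variable == "hold" and self.v_pulse is None:
            raise ValueError("sweeping the hold level requires v_pulse")
        self.active: Quantity = self.sweep[0]

    @property
    def period(self) -> float:
        return self.t_hold.si + self.t_pulse.si

    def levels_si(self) -> tuple[float, float]:
        """(holding level, pulse level) for the active sweep value, SI."""
        if self.sweep_variable == "pulse":
            return self.v_hold.si, self.active.si
        return self.active.si, self.v_pulse.si  # type: ignore[union-attr]

    def value_si(self, t: float) -> float:
        hold, pulse = self.levels_si()
        phase = math.fmod(t, self.period)
        if phase < 0:
            phase += self.period
        return pulse if phase >= self.t_hold.si else hold

    def discontinuities(self, t0: float, t1: float) -> list[float]:
        out = []
        k = math.floor(t0 / self.period)
        while k * self.period <= t1:
            for tb in (k * self.period, k * self.period + self.t_hold.si):
                if t0 < tb < t1:
                    out.append(tb)
            k += 1
        return out


@dataclass
class CurrentPulseProtocol:
    """Repeated current pulses: I_pulse during the final T_pulse per cycle."""

    t_hold: Quantity
    t_pulse: Quantity
    i_pulse: Quantity

    def __post_init__(self) -> None:
        if self.t_pulse.si <= 0 or self.t_hold.si <= 0:
            raise ValueError("T_hold and T_pulse must be positive")
        if self.t_pulse.si >= self.t_hold.si:
            raise ValueError("T_pulse must be smaller than T_hold")
        if self.i_pulse.signature != _AMPERE:
            raise ValueError("I_pulse must carry ampere units")

    @property
    def period(self) -> float:
        return self.t_hold.si + self.t_pulse.si

    def value_si(self, t: float) -> float:
        phase = math.fmod(t, self.period)
        if phase < 0:
            phase += self.period
        return self.i_pulse.si if phase >= self.t_hold.si else 0.0

    def discontinuities(self, t0: float, t1: float) -> list[float]:
        out = []
        k = math.floor(t0 / self.period)
        while k * self.period <= t1:
            for tb in (k * self.period, k * self.period + self.t_hold.si):
                if t0 < tb < t1:
                    out.append(tb)
            k += 1
        return out


def protocol_drive(
    p: TestPulseProtocol | CurrentPulseProtocol, t: Quantity | float
) -> Quantity:
    """The piecewise-constant protocol signal at time ``t`` (V or A)."""
    t_si = _si(t, _TIME, "t")
    unit = "A" if isinstance(p, CurrentPulseProtocol) else "V"
    return quantity(p.value_si(t_si), unit)


@dataclass(frozen=True)
class IVCurve:
    """Swept potential vs extracted peak current, strictly ordered."""

    potentials: tuple[float, ...]  # SI volts
    currents: tuple[float, ...]  # SI amperes

    def __post_init__(self) -> None:
        if len(self.potentials) != len(self.currents):
            raise ValueError("potential/current length mismatch")
        if any(
            b <= a for a, b in zip(self.potentials, self.potentials[1:])
        ):
            raise ValueError("swept potentials must be strictly increasing")

    def __len__(self) -> int:
        return len(self.potentials)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.potentials), np.asarray(self.currents)


def extract_peak(
    trace: Trajectory,
    measure: str,
    window: tuple[float, float],
    peak_mode: str = "magnitude",
) -> Quantity:
    """Extract the peak current of a trace inside a time window.

    ``peak_mode``: "magnitude" (signed value of largest magnitude, the
    default), "max", or "min".
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty peak window")
    t = trace.time
    mask = (t >= t0 - 1e-15) & (t <= t1 + 1e-15)
    if not mask.any():
        raise ValueError(
            f"peak window [{t0}, {t1}] contains no trace samples"
        )
    vals = trace[measure][mask]
    if peak_mode == "magnitude":
        peak = vals[np.argmax(np.abs(vals))]
    elif peak_mode == "max":
        peak = vals.max()
    elif peak_mode == "min":
        peak = vals.min()
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    return quantity(float(peak), "A")


def _find_clamp(graph: ComponentGraph, p) -> VoltageSource:
    clamps = [
        c
        for c in graph.components.values()
        if isinstance(c, VoltageSource) and c.drive is p
    ]
    if len(clamps) != 1:
        raise ProtocolError(
            "run_iv requires exactly one voltage source bound to the "
            f"protocol, found {len(clamps)}"
        )
    return clamps[0]


def run_iv(
    graph: ComponentGraph,
    p: TestPulseProtocol,
    measure: str,
    interval: float = 2e-5,
    tolerance: float = 1e-10,
    mode: str = "independent",
    peak_mode: str = "magnitude",
    full_cycle: bool = False,
) -> IVCurve:
    """Run the test-pulse protocol over its sweep and extract the I-V curve.

    Per sweep value the system is relaxed at the holding level for T_hold
    (``mode="independent"``, the default: no carry-over between sweeps) or
    carried over from the previous cycle (``mode="sequential"``), then the
    pulse is simulated and the peak extracted over the pulse window (or
    the whole cycle with ``full_cycle=True``).
    """
    clamp = _find_clamp(graph, p)
    sys = graph.assemble()
    order = sorted(range(len(p.sweep)), key=lambda i: p.sweep[i].si)
    pots: list[float] = []
    peaks: list[float] = []
    y = np.array(sys.y0, dtype=float)
    for i in order:
        p.active = p.sweep[i]
        hold, pulse = p.levels_si()
        swept = p.active.si if p.sweep_variable == "pulse" else hold
        try:
            clamp.drive = hold
            if mode == "independent":
                init = initialize_steady(
                    sys, p.t_hold.si, tolerance=math.inf
                )
                y_start = init.state
            elif mode == "sequential":
                init = initialize_steady(
                    sys, p.t_hold.si, y0=y, tolerance=math.inf
                )
                y_start = init.state
            else:
                raise ValueError(f"unknown mode {mode!r}")
            clamp.drive = pulse
            horizon = p.t_pulse.si + (p.t_hold.si if full_cycle else 0.0)
            settings = SolverSettings(
                start=0.0,
                stop=horizon,
                tolerance=tolerance,
                interval=interval,
            )
            traj = simulate(sys, settings, y0=y_start)
            peak = extract_peak(
                traj, measure, (0.0, horizon), peak_mode=peak_mode
            )
            y = traj.data.iloc[-1][sys.state_names].to_numpy(dtype=float)
        except Exception as exc:
            if isinstance(exc, (ValueError, KeyError)):
                raise
            raise ProtocolError(
                f"protocol failed at sweep value {swept} V: {exc}"
            ) from exc
        finally:
            clamp.drive = p
        pots.append(swept)
        peaks.append(peak.si)
    return IVCurve(tuple(pots), tuple(peaks))
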