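"""Ion-channel primitives: electric-analog base, open-ratio algebra, GHK flux.

Nearly every channel in the AV-node cell family follows an electric analog:
a gated conductance in series with an equilibrium-potential source,

    i = open_ratio * g_max * (v - v_eq)

with the outward-positive sign convention (positive pin extracellular).
The open ratio is a small algebraic composition over gate states — powers
of a single gate and convex weighted sums of gates — expressed either
programmatically or as a config string such as
``"act^3 * (0.635*fast + 0.365*slow)"``.

The sodium current instead follows the Goldman-Hodgkin-Katz (GHK) flux
equation, which has a removable singularity at 0 mV; :func:`ghk_current`
patches it with a Taylor expansion so the current is continuous there.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Mapping

from .kinetics import GateAB, GateTS
from .quantities import (
    Quantity,
    parse_unit,
    quantity,
)

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "OpenRatioExpr",
    "ElectricChannel",
    "GHKChannel",
    "electric_current",
    "sodium_open_ratio",
    "ghk_current",
]

#: Faraday constant (CODATA), C/mol.
FARADAY = 96485.33212
#: Molar gas constant (CODATA), J/(mol K).
GAS_CONSTANT = 8.31446261815324

_AMPERE = parse_unit("A").signature
_SIEMENS = parse_unit("S").signature
_VOLT = parse_unit("V").signature
_CONC = parse_unit("mM").signature
_PERM_VOL = parse_unit("m^3/s").signature  # permeability x membrane area


# ---------------------------------------------------------------------------
# open-ratio expressions
# ---------------------------------------------------------------------------

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Name,
    ast.Constant,
    ast.Add,
    ast.Mult,
    ast.Pow,
    ast.USub,
    ast.Load,
)


class OpenRatioExpr:
    """A composition tree over gate states.

    Grammar: gate names, nonnegative numeric literals, ``+``, ``*``, ``^``
    (or ``**``), and parentheses.  Evaluates in [0, 1] whenever the leaves
    do, provided sums are convex and exponents >= 1 — which
    :meth:`validate` checks by evaluating on the corners of the unit cube.
    """

    def __init__(self, expression: str):
        self.expression = expression
        src = expression.replace("^", "**")
        tree = ast.parse(src, mode="eval")
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ValueError(
                    f"open-ratio expression {expression!r}: "
                    f"unsupported construct {type(node).__name__}"
                )
            if isinstance(node, ast.Constant) and not isinstance(
                node.value, (int, float)
            ):
                raise ValueError(
                    f"open-ratio expression {expression!r}: "
                    f"non-numeric constant {node.value!r}"
                )
        self._code = compile(tree, "<open_ratio>", "eval")
        self.gate_names = tuple(
            sorted(
                {
                    node.id
                    for node in ast.walk(tree)
                    if isinstance(node, ast.Name)
                }
            )
        )

    def __call__(self, gates: Mapping[str, float]) -> float:
        return float(eval(self._code, {"__builtins__": {}}, dict(gates)))

    def validate(self) -> None:
        """Check the [0,1] invariant on all corners of the gate unit cube."""
        k = len(self.gate_names)
        for mask in range(2**k):
            corner = {
                name: float((mask >> j) & 1)
                for j, name in enumerate(self.gate_names)
            }
            val = self(corner)
            if not -1e-12 <= val <= 1.0 + 1e-12:
                raise ValueError(
                    f"open-ratio expression {self.expression!r} leaves [0,1] "
                    f"at corner {corner} (value {val})"
                )

    def __repr__(self) -> str:
        return f"OpenRatioExpr({self.expression!r})"


def sodium_open_ratio(act: float, fast: float, slow: float) -> float:
    """Sodium-channel open ratio: cubed activation times total inactivation.

    The total inactivation is the convex mix 0.635*fast + 0.365*slow of the
    fast and slow inactivation gates, so the result stays in [0, 1].
    """
    return act**3 * (0.635 * fast + 0.365 * slow)


# ---------------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------------

@dataclass
class ElectricChannel:
    """Electric-analog ion channel: gated conductance + equilibrium source."""

    name: str
    g_max: Quantity
    v_eq: Quantity
    gates: dict[str, GateTS | GateAB] = field(default_factory=dict)
    open_ratio: OpenRatioExpr | None = None

    def __post_init__(self) -> None:
        if self.g_max.signature != _SIEMENS:
            raise ValueError(
                f"channel {self.name}: g_max must be a conductance, "
                f"got {self.g_max.signature}"
            )
        if self.v_eq.signature != _VOLT:
            raise ValueError(
                f"channel {self.name}: v_eq must be a voltage, "
                f"got {self.v_eq.signature}"
            )
        if self.g_max.si < 0:
            raise ValueError(f"channel {self.name}: g_max must be >= 0")
        if self.open_ratio is not None:
            missing = set(self.open_ratio.gate_names) - set(self.gates)
            if missing:
                raise ValueError(
                    f"channel {self.name}: open-ratio references unknown "
                    f"gates {sorted(missing)}"
                )

    def evaluate_open_ratio(
        self, gate_values: Mapping[str, float] | None = None
    ) -> float:
        values = (
            {name: g.n for name, g in self.gates.items()}
            if gate_values is None
            else dict(gate_values)
        )
        if self.open_ratio is None:
            return 1.0 if not values else math.prod(values.values())
        return self.open_ratio(values)

    def current_si(self, v: float, open_ratio: float) -> float:
        return open_ratio * self.g_max.si * (v - self.v_eq.si)


def electric_current(
    ch: ElectricChannel,
    v: Quantity | float,
    gate_values: Mapping[str, float] | None = None,
) -> Quantity:
    """Outward-positive channel current i = open_ratio*g_max*(v - v_eq)."""
    v_si = v.si if isinstance(v, Quantity) else float(v)
    ratio = ch.evaluate_open_ratio(gate_values)
    return quantity(ch.current_si(v_si, ratio), "A")


@dataclass
class GHKChannel:
    """Ion channel whose current follows the GHK flux equation.

    The permeability is configured as a single quantity ``p_area`` with
    signature volume/time (permeability times membrane area), which is the
    dimensional contract that makes the current come out in amperes:
    (m^3/s) x (C/mol) x (mol/m^3) = A.
    """

    name: str
    p_area: Quantity
    z: int
    c_in: Quantity
    c_out: Quantity
    temperature: Quantity = field(
        default_factory=lambda: quantity(310.0, "K")
    )
    gates: dict[str, GateTS | GateAB] = field(default_factory=dict)
    open_ratio: OpenRatioExpr | None = None

    def __post_init__(self) -> None:
        if self.p_area.signature != _PERM_VOL:
            raise ValueError(
                f"channel {self.name}: p_area must have signature m^3/s "
                f"(permeability x area), got {self.p_area.signature}"
            )
        for label, c in (("c_in", self.c_in), ("c_out", self.c_out)):
            if c.signature != _CONC:
                raise ValueError(
                    f"channel {self.name}: {label} must be a concentration"
                )
            if c.si <= 0:
                raise ValueError(
                    f"channel {self.name}: {label} must be positive"
                )
        if self.z == 0:
            raise ValueError(f"channel {self.name}: valence must be nonzero")
        if self.temperature.si <= 0:
            raise ValueError(
                f"channel {self.name}: temperature must be positive"
            )

    @property
    def nernst_potential(self) -> Quantity:
        """Equilibrium potential (RT/zF) ln(c_out/c_in); current is 0 there."""
        rt_zf = (
            GAS_CONSTANT
            * self.temperature.si
            / (self.z * FARADAY)
        )
        return quantity(
            rt_zf * math.log(self.c_out.si / self.c_in.si), "V"
        )

    def evaluate_open_ratio(
        self, gate_values: Mapping[str, float] | None = None
    ) -> float:
        values = (
            {name: g.n for name, g in self.gates.items()}
            if gate_values is None
            else dict(gate_values)
        )
        if self.open_ratio is None:
            return 1.0 if not values else math.prod(values.values())
        return self.open_ratio(values)

    def current_si(self, v: float, open_ratio: float = 1.0) -> float:
        u = self.z * v * FARADAY / (GAS_CONSTANT * self.temperature.si)
        cin, cout = self.c_in.si, self.c_out.si
        driving = cin - cout * math.exp(-u)
        if abs(u) < 1e-4:
            # 2nd-order Taylor patch of u/(1 - exp(-u)) around u = 0;
            # relative error < 1e-9 at the switch point
            ratio = 1.0 + u / 2.0 + u * u / 12.0
        else:
            ratio = u / (1.0 - math.exp(-u))
        return open_ratio * self.p_area.si * self.z * FARADAY * driving * ratio


def ghk_current(
    ch: GHKChannel,
    v: Quantity | float,
    gate_values: Mapping[str, float] | None = None,
) -> Quantity:
    """GHK current, continuous at v = 0 and zero at the Nernst potential.

    At v = 0 the value is the limit p_area*z*F*(c_in - c_out); the avoidable
    discontinuity is patched by a Taylor expansion declared and unit-tested
    for continuity, the policy this kit applies to every rate expression
    with a removable singularity.
    """
    v_si = v.si if isinstance(v, Quantity) else float(v)
    ratio = ch.evaluate_open_ratio(gate_values)
    return quantity(ch.current_si(v_si, ratio), "A")
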