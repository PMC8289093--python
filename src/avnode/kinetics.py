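"""Fitting functions and first-order Hodgkin-Huxley gate primitives.

A Hodgkin-Huxley (HH) gate tracks the fraction ``n`` of a channel's gating
structures in the open conformation.  Two equivalent parameterizations are
supported:

* :class:`GateTS` — a steady state n_inf(v) and a time constant tau(v),
  with dn/dt = (n_inf(v) - n) / tau(v);
* :class:`GateAB` — voltage-dependent opening/closing rates alpha(v),
  beta(v), with dn/dt = alpha(v)*(1 - n) - beta(v)*n.

:func:`ab_steady_tau` maps the second form onto the first
(n_inf = a/(a+b), tau = 1/(a+b)).

The workhorse fitting function for steadies and time constants is the
generalized logistic :func:`gen_logistic`:

    y(v) = y_min + (y_max - y_min) / (1 + exp(-sx*(v - x0)))

where x0 is the inflection point and the sign of sx sets the direction
(sx < 0 gives a declining sigmoid).  For the fast-inactivation time
constant of the sodium current this reproduces the published asymptotes of
0.35 ms (strong depolarization) and 30.35 ms (strong hyperpolarization)
with maximal steepness at -40 mV.

Voltage-level functions accept and return :class:`~avnode.quantities.Quantity`;
the underscore-suffixed kernels (``gen_logistic_f`` etc.) operate on plain
SI floats and are what the ODE right-hand sides call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .quantities import (
    DIMENSIONLESS,
    Quantity,
    UnitSignature,
    parse_unit,
    quantity,
)

__all__ = [
    "GenLogisticParams",
    "GateTS",
    "GateAB",
    "gen_logistic",
    "gen_logistic_f",
    "gate_rhs",
    "ab_steady_tau",
    "constant_fn",
    "fitting_function_from_config",
    "FITTING_FUNCTIONS",
]

_VOLT = parse_unit("V").signature
_PER_SECOND = parse_unit("1/s").signature
_SECOND = parse_unit("s").signature

# exp() argument clamp: beyond +-700 the double-precision logistic is
# saturated anyway and exp would overflow.
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class GenLogisticParams:
    """Parameters of the generalized logistic fit.

    y_min/y_max share a signature (the output unit, e.g. seconds for a time
    constant); x0 is a voltage; sx an inverse voltage whose sign sets the
    direction of the sigmoid.
    """

    y_min: Quantity
    y_max: Quantity
    x0: Quantity
    sx: Quantity

    def __post_init__(self) -> None:
        if self.y_min.signature != self.y_max.signature:
            raise ValueError("y_min and y_max must share a unit signature")
        if self.sx.si == 0:
            raise ValueError("sx must be nonzero")

    @classmethod
    def in_si(
        cls,
        y_min: float,
        y_max: float,
        x0: float,
        sx: float,
        y_unit: str = "s",
    ) -> "GenLogisticParams":
        return cls(
            quantity(y_min, y_unit),
            quantity(y_max, y_unit),
            quantity(x0, "V"),
            quantity(sx, "1/V"),
        )


def gen_logistic_f(
    v: float, y_min: float, y_max: float, x0: float, sx: float
) -> float:
    """SI-float kernel of the generalized logistic."""
    u = sx * (v - x0)
    u = max(-_EXP_CLAMP, min(_EXP_CLAMP, u))
    return y_min + (y_max - y_min) / (1.0 + math.exp(-u))


def gen_logistic(v: Quantity | float, p: GenLogisticParams) -> Quantity:
    """Evaluate the generalized logistic at membrane potential ``v``.

    The value lies strictly between y_min and y_max, is monotone in ``v``
    with the sign of sx, and equals the midpoint at v = x0.
    """
    v_si = v.si if isinstance(v, Quantity) else float(v)
    y = gen_logistic_f(v_si, p.y_min.si, p.y_max.si, p.x0.si, p.sx.si)
    return Quantity(y, p.y_min.unit)


def constant_fn(q: Quantity) -> Callable[[float], float]:
    """A constant fitting-function slot (SI in, SI out) tagged with units."""

    def fn(v: float) -> float:
        return q.si

    fn.output_signature = q.signature  # type: ignore[attr-defined]
    return fn


def _tag(fn: Callable[[float], float], sig: UnitSignature):
    fn.output_signature = sig  # type: ignore[attr-defined]
    return fn


@dataclass
class GateTS:
    """First-order HH gate in steady-state / time-constant form.

    ``fsteady`` and ``ftau`` map an SI membrane potential (V) to a
    dimensionless open fraction and a time constant in seconds.  They are
    pluggable slots: any callable tagged with an ``output_signature`` keeps
    the unit auditor informed (functions built from :class:`GenLogisticParams`
    via :meth:`from_logistic` come pre-tagged).
    """

    name: str
    fsteady: Callable[[float], float]
    ftau: Callable[[float], float]
    n: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.n <= 1.0:
            raise ValueError(f"gate {self.name}: n={self.n} outside [0, 1]")

    @classmethod
    def from_logistic(
        cls,
        name: str,
        steady: GenLogisticParams,
        tau: GenLogisticParams,
        n0: float | None = None,
    ) -> "GateTS":
        if steady.y_min.signature != DIMENSIONLESS:
            raise ValueError("steady-state fit must be dimensionless")
        if tau.y_min.signature != _SECOND:
            raise ValueError("time-constant fit must be in seconds")
        fsteady = _tag(
            lambda v: gen_logistic_f(
                v, steady.y_min.si, steady.y_max.si, steady.x0.si, steady.sx.si
            ),
            DIMENSIONLESS,
        )
        ftau = _tag(
            lambda v: gen_logistic_f(
                v, tau.y_min.si, tau.y_max.si, tau.x0.si, tau.sx.si
            ),
            _SECOND,
        )
        # default initial state: fsteady(0), the relaxed state at 0 V
        n = fsteady(0.0) if n0 is None else n0
        return cls(name, fsteady, ftau, n)

    def steady_signature(self) -> UnitSignature:
        return getattr(self.fsteady, "output_signature", DIMENSIONLESS)

    def tau_signature(self) -> UnitSignature:
        return getattr(self.ftau, "output_signature", _SECOND)

    def rhs(self, n: float, v: float) -> float:
        """dn/dt (1/s) at state ``n`` and SI membrane potential ``v``."""
        tau = self.ftau(v)
        if tau <= 0.0:
            raise ValueError(
                f"gate {self.name}: nonpositive time constant tau({v})={tau}"
            )
        return (self.fsteady(v) - n) / tau


@dataclass
class GateAB:
    """First-order HH gate in alpha/beta rate form (rates in 1/s)."""

    name: str
    alpha: Callable[[float], float]
    beta: Callable[[float], float]
    n: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.n <= 1.0:
            raise ValueError(f"gate {self.name}: n={self.n} outside [0, 1]")

    def rhs(self, n: float, v: float) -> float:
        return self.alpha(v) * (1.0 - n) - self.beta(v) * n

    def as_ts(self) -> GateTS:
        """The induced steady/time-constant gate (same dynamics)."""

        def fsteady(v: float) -> float:
            a, b = self.alpha(v), self.beta(v)
            return a / (a + b)

        def ftau(v: float) -> float:
            return 1.0 / (self.alpha(v) + self.beta(v))

        return GateTS(
            self.name, _tag(fsteady, DIMENSIONLESS), _tag(ftau, _SECOND), self.n
        )

    # the unit auditor treats alpha/beta as rates
    def steady_signature(self) -> UnitSignature:
        return DIMENSIONLESS

    def tau_signature(self) -> UnitSignature:
        return _SECOND


def gate_rhs(g: GateTS | GateAB, v: Quantity | float) -> Quantity:
    """Time derivative of the gate's open fraction at potential ``v``.

    Zero exactly when the gate sits at its voltage-dependent steady state.
    """
    v_si = v.si if isinstance(v, Quantity) else float(v)
    return quantity(g.rhs(g.n, v_si), "1/s")


def ab_steady_tau(g: GateAB, v: Quantity | float) -> tuple[float, Quantity]:
    """Steady state and time constant induced by alpha/beta rates.

    steady = a/(a+b) in [0,1]; tau = 1/(a+b) > 0.  The induced GateTS
    right-hand side (steady - n)/tau is algebraically a*(1-n) - b*n.
    """
    v_si = v.si if isinstance(v, Quantity) else float(v)
    a, b = g.alpha(v_si), g.beta(v_si)
    if a < 0 or b < 0:
        raise ValueError(f"gate {g.name}: negative rate at v={v_si}")
    total = a + b
    if total == 0.0:
        raise ZeroDivisionError(
            f"gate {g.name}: degenerate rates alpha+beta=0 at v={v_si}"
        )
    return a / total, quantity(1.0 / total, "s")


# ---------------------------------------------------------------------------
# config-facing fitting-function registry
# ---------------------------------------------------------------------------

def _gen_logistic_from_config(spec: dict) -> Callable[[float], float]:
    y_unit = spec.get("y_unit", "1")
    p = GenLogisticParams(
        quantity(spec["y_min"], y_unit),
        quantity(spec["y_max"], y_unit),
        quantity(spec["x0"], spec.get("x_unit", "V")),
        quantity(spec["sx"], f"1/({spec.get('x_unit', 'V')})"),
    )
    return _tag(
        lambda v: gen_logistic_f(v, p.y_min.si, p.y_max.si, p.x0.si, p.sx.si),
        p.y_min.signature,
    )


def _constant_from_config(spec: dict) -> Callable[[float], float]:
    return constant_fn(quantity(spec["value"], spec.get("y_unit", "1")))


#: Named fitting-function families available to config files.  Users may
#: register additional families; anything tagged with an output signature
#: stays visible to the unit auditor.
FITTING_FUNCTIONS: dict[str, Callable[[dict], Callable[[float], float]]] = {
    "genLogistic": _gen_logistic_from_config,
    "constant": _constant_from_config,
}


def fitting_function_from_config(spec: dict) -> Callable[[float], float]:
    """Build a fitting function from a ``{"fn": name, ...}`` config block."""
    name = spec["fn"]
    if name not in FITTING_FUNCTIONS:
        raise KeyError(
            f"unknown fitting function {name!r}; "
            f"known: {sorted(FITTING_FUNCTIONS)}"
        )
    return FITTING_FUNCTIONS[name](spec)
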