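"""Four-state Na+/Ca2+ exchanger: analytic steady-state current.

The exchanger is modeled as a cycle over four carrier states whose
steady-state occupancies admit a closed form: the unnormalized weights
x1..x4 are cubic polynomials in the eight transition rates (the analytic
null space of the 4-state master equation), and only the 1<->2 edge is
electrogenic, so the current is the net flux across that single edge:

    I_NaCa = k_NaCa * (k21*x2 - k12*x1) / (x1 + x2 + x3 + x4)

The rate constants are plain inputs here; their dependence on membrane
potential and Na/Ca concentrations is supplied by a pluggable rate
provider (see :class:`RateProvider`), since those laws live in the cited
literature rather than in this kit's sources.  The component deliberately
stays monolithic: the analytic solution cannot be reassembled from
separate per-edge diffusion components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from .quantities import Quantity, parse_unit, quantity

__all__ = [
    "FourStateRates",
    "ExchangerState",
    "RateProvider",
    "x_terms",
    "state_fractions",
    "naca_current",
]

_PER_SECOND = parse_unit("1/s").signature
_AMPERE = parse_unit("A").signature

RATE_NAMES = ("k12", "k21", "k23", "k32", "k34", "k43", "k14", "k41")

#: A pluggable provider mapping (membrane potential [V], concentrations)
#: to the eight rates in 1/s.
RateProvider = Callable[[float, Mapping[str, float]], "FourStateRates"]


def _rate(value: float | Quantity, name: str) -> float:
    if isinstance(value, Quantity):
        if value.signature != _PER_SECOND:
            raise ValueError(f"rate {name} must have signature 1/s")
        value = value.si
    value = float(value)
    if value < 0:
        raise ValueError(f"rate {name} must be >= 0, got {value}")
    return value


@dataclass(frozen=True)
class FourStateRates:
    """The eight transition rates of the 4-state cycle, in 1/s, each >= 0."""

    k12: float
    k21: float
    k23: float
    k32: float
    k34: float
    k43: float
    k14: float
    k41: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            object.__setattr__(self, name, _rate(getattr(self, name), name))

    def scaled(self, c: float) -> "FourStateRates":
        return FourStateRates(
            *(c * getattr(self, name) for name in RATE_NAMES)
        )


@dataclass(frozen=True)
class ExchangerState:
    """Occupancy fractions E1..E4 of the four carrier states (sum to 1)."""

    E1: float
    E2: float
    E3: float
    E4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.E1, self.E2, self.E3, self.E4)


def x_terms(k: FourStateRates) -> tuple[float, float, float, float]:
    """Unnormalized steady-state weights of the four states.

    These are the published closed-form polynomials; normalized they equal
    the null-space vector of the master-equation rate matrix.
    """
    x1 = k.k34 * k.k41 * (k.k23 + k.k21) + k.k21 * k.k32 * (k.k43 + k.k41)
    x2 = k.k43 * k.k32 * (k.k14 + k.k12) + k.k41 * k.k12 * (k.k34 + k.k32)
    x3 = k.k43 * k.k14 * (k.k23 + k.k21) + k.k12 * k.k23 * (k.k43 + k.k41)
    x4 = k.k34 * k.k23 * (k.k14 + k.k12) + k.k21 * k.k14 * (k.k34 + k.k32)
    return (x1, x2, x3, x4)


def state_fractions(x: tuple[float, float, float, float]) -> ExchangerState:
    """Normalize the x-terms into occupancy fractions summing to one."""
    total = sum(x)
    if total <= 0.0:
        raise ZeroDivisionError(
            "degenerate kinetics: all steady-state weights are zero"
        )
    return ExchangerState(*(xi / total for xi in x))


def naca_current(k: FourStateRates, k_naca: Quantity) -> Quantity:
    """Steady-state exchanger current from the net flux on the 1<->2 edge.

    ``k_naca`` carries ampere units (a density given in pA/pF is first
    multiplied by the membrane capacitance, per the registry's conversion
    rule).  The current vanishes exactly when the cycle satisfies detailed
    balance (k12*k23*k34*k41 == k21*k32*k43*k14), and is invariant under a
    common rescaling of all eight rates.
    """
    if k_naca.signature != _AMPERE:
        raise ValueError(
            f"k_NaCa must carry ampere units, got {k_naca.signature}"
        )
    x = x_terms(k)
    total = sum(x)
    if total <= 0.0:
        raise ZeroDivisionError(
            "degenerate kinetics: all steady-state weights are zero"
        )
    return quantity(
        k_naca.si * (k.k21 * x[1] - k.k12 * x[0]) / total, "A"
    )
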