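"""SI unit signatures, conversions, and dimensional-consistency checking.

Every numeric value that crosses a module boundary in this kit is a
:class:`Quantity`: a float bound to a seven-dimensional SI unit signature.
Model equations are audited for dimensional consistency by comparing the
signatures of their two sides (:func:`check_equation`), and an assembled
component graph can be audited equation-by-equation
(:func:`audit_model_units`) so that order-of-magnitude errors from missed
unit conversions (the classic ms vs s slip) are caught mechanically rather
than by eye.

Values are stored canonically in strict SI; display units (the cardiac
dialect: mV, nA, pA, nS, pF, mM, ms, nl, pl, ...) only affect how a value
is rendered and parsed.  Unit strings use a plain-text grammar with
product ``.``, division ``/`` and power ``^``, e.g. ``"1/(mM.s)"`` or
``"m/s"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Union

__all__ = [
    "DIMENSIONS",
    "UnitSignature",
    "Unit",
    "Quantity",
    "ConsistencyVerdict",
    "DimensionError",
    "UnitParseError",
    "parse_unit",
    "register_unit",
    "quantity",
    "convert",
    "check_equation",
    "audit_model_units",
    "DIMENSIONLESS",
]

#: The seven SI base dimensions, in the order used by signature tuples.
DIMENSIONS = ("kg", "m", "s", "A", "K", "mol", "cd")


class DimensionError(ValueError):
    """Raised when an operation mixes incommensurable unit signatures."""


class UnitParseError(ValueError):
    """Raised when a unit string does not follow the ``.``/``/``/``^`` grammar."""


def _coerce_exponents(exponents) -> tuple[Fraction, ...]:
    exps = tuple(Fraction(e) for e in exponents)
    if len(exps) != len(DIMENSIONS):
        raise ValueError(f"expected {len(DIMENSIONS)} exponents, got {len(exps)}")
    return exps


@dataclass(frozen=True)
class UnitSignature:
    """Exponents over the seven SI base dimensions.

    Signature equality is exponent equality; the optional display name is
    cosmetic only.  Rational exponents are allowed for robustness, although
    every shipped component uses integer exponents.
    """

    exponents: tuple[Fraction, ...]
    name: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exponents", _coerce_exponents(self.exponents))

    def __mul__(self, other: "UnitSignature") -> "UnitSignature":
        return UnitSignature(
            tuple(a + b for a, b in zip(self.exponents, other.exponents))
        )

    def __truediv__(self, other: "UnitSignature") -> "UnitSignature":
        return UnitSignature(
            tuple(a - b for a, b in zip(self.exponents, other.exponents))
        )

    def __pow__(self, power) -> "UnitSignature":
        p = Fraction(power)
        return UnitSignature(tuple(a * p for a in self.exponents))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnitSignature):
            return NotImplemented
        return self.exponents == other.exponents

    def __hash__(self) -> int:
        return hash(self.exponents)

    @property
    def is_dimensionless(self) -> bool:
        return all(e == 0 for e in self.exponents)

    def __str__(self) -> str:
        if self.name:
            return self.name
        if self.is_dimensionless:
            return "1"
        num = [
            f"{d}" + (f"^{e}" if e != 1 else "")
            for d, e in zip(DIMENSIONS, self.exponents)
            if e > 0
        ]
        den = [
            f"{d}" + (f"^{-e}" if e != -1 else "")
            for d, e in zip(DIMENSIONS, self.exponents)
            if e < 0
        ]
        head = ".".join(num) if num else "1"
        return head + ("/" + ".".join(den) if den else "")


def _sig(**dims) -> UnitSignature:
    return UnitSignature(tuple(Fraction(dims.get(d, 0)) for d in DIMENSIONS))


DIMENSIONLESS = _sig()


@dataclass(frozen=True)
class Unit:
    """A display unit: a signature plus the exact scale factor to SI."""

    signature: UnitSignature
    scale: float
    name: str

    def __str__(self) -> str:
        return self.name


_UNIT_REGISTRY: dict[str, Unit] = {}


def register_unit(name: str, signature: UnitSignature, scale: float = 1.0) -> Unit:
    """Register a named display unit; returns the :class:`Unit`."""
    unit = Unit(UnitSignature(signature.exponents, name), float(scale), name)
    _UNIT_REGISTRY[name] = unit
    return unit


def _register_defaults() -> None:
    base = {
        "kg": _sig(kg=1),
        "m": _sig(m=1),
        "s": _sig(s=1),
        "A": _sig(A=1),
        "K": _sig(K=1),
        "mol": _sig(mol=1),
        "cd": _sig(cd=1),
    }
    for name, sig in base.items():
        register_unit(name, sig)
    register_unit("g", _sig(kg=1), 1e-3)
    volt = _sig(kg=1, m=2, s=-3, A=-1)
    coulomb = _sig(A=1, s=1)
    siemens = _sig(kg=-1, m=-2, s=3, A=2)
    farad = _sig(kg=-1, m=-2, s=4, A=2)
    register_unit("V", volt)
    register_unit("C", coulomb)
    register_unit("S", siemens)
    register_unit("F", farad)
    register_unit("J", _sig(kg=1, m=2, s=-2))
    register_unit("Hz", _sig(s=-1))
    register_unit("N", _sig(kg=1, m=1, s=-2))
    # cardiac dialect
    register_unit("mV", volt, 1e-3)
    register_unit("uV", volt, 1e-6)
    register_unit("nA", _sig(A=1), 1e-9)
    register_unit("pA", _sig(A=1), 1e-12)
    register_unit("nS", siemens, 1e-9)
    register_unit("uS", siemens, 1e-6)
    register_unit("pF", farad, 1e-12)
    register_unit("nF", farad, 1e-9)
    register_unit("ms", _sig(s=1), 1e-3)
    register_unit("us", _sig(s=1), 1e-6)
    # 1 mM = 1 mmol/l = 1 mol/m^3, exactly
    register_unit("mM", _sig(mol=1, m=-3), 1.0)
    register_unit("M", _sig(mol=1, m=-3), 1e3)
    register_unit("mmol", _sig(mol=1), 1e-3)
    register_unit("l", _sig(m=3), 1e-3)
    register_unit("ml", _sig(m=3), 1e-6)
    register_unit("ul", _sig(m=3), 1e-9)
    register_unit("nl", _sig(m=3), 1e-12)
    register_unit("pl", _sig(m=3), 1e-15)


_register_defaults()


# ---------------------------------------------------------------------------
# unit-string grammar: product ".", division "/", power "^", parentheses
# ---------------------------------------------------------------------------

def _tokenize(text: str) -> Iterator[str]:
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "./^()":
            yield ch
            i += 1
        elif ch == "-" or ch.isdigit():
            j = i + 1
            while j < len(text) and text[j].isdigit():
                j += 1
            yield text[i:j]
            i = j
        elif ch.isalpha():
            j = i + 1
            while j < len(text) and text[j].isalnum():
                j += 1
            yield text[i:j]
            i = j
        else:
            raise UnitParseError(f"unexpected character {ch!r} in unit {text!r}")
    yield ""  # sentinel


class _UnitParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> str:
        return self.tokens[self.pos]

    def advance(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> tuple[UnitSignature, float]:
        sig, scale = self.expr()
        if self.peek() != "":
            raise UnitParseError(
                f"trailing input {self.peek()!r} in unit {self.text!r}"
            )
        return sig, scale

    def expr(self) -> tuple[UnitSignature, float]:
        sig, scale = self.factor()
        while self.peek() in (".", "/"):
            op = self.advance()
            s2, c2 = self.factor()
            if op == ".":
                sig, scale = sig * s2, scale * c2
            else:
                sig, scale = sig / s2, scale / c2
        return sig, scale

    def factor(self) -> tuple[UnitSignature, float]:
        sig, scale = self.atom()
        if self.peek() == "^":
            self.advance()
            tok = self.advance()
            try:
                power = int(tok)
            except ValueError as exc:
                raise UnitParseError(
                    f"expected integer exponent, got {tok!r} in {self.text!r}"
                ) from exc
            sig = sig**power
            scale = scale**power
        return sig, scale

    def atom(self) -> tuple[UnitSignature, float]:
        tok = self.advance()
        if tok == "(":
            sig, scale = self.expr()
            if self.advance() != ")":
                raise UnitParseError(f"unbalanced parentheses in {self.text!r}")
            return sig, scale
        if tok == "1":
            return DIMENSIONLESS, 1.0
        if tok in _UNIT_REGISTRY:
            unit = _UNIT_REGISTRY[tok]
            return unit.signature, unit.scale
        raise UnitParseError(f"unknown unit {tok!r} in {self.text!r}")


def parse_unit(text: str) -> Unit:
    """Parse a unit string of the ``"1/(mM.s)"`` dialect into a :class:`Unit`."""
    if text in _UNIT_REGISTRY:
        return _UNIT_REGISTRY[text]
    sig, scale = _UnitParser(text).parse()
    return Unit(UnitSignature(sig.exponents, text), scale, text)


UnitLike = Union[Unit, UnitSignature, str]


def _as_unit(u: UnitLike) -> Unit:
    if isinstance(u, Unit):
        return u
    if isinstance(u, str):
        return parse_unit(u)
    if isinstance(u, UnitSignature):
        return Unit(u, 1.0, u.name or str(u))
    raise TypeError(f"not a unit: {u!r}")


@dataclass(frozen=True)
class Quantity:
    """A float bound to a unit signature, stored canonically in SI.

    ``value`` is the magnitude in the display ``unit``; ``si`` is the
    canonical SI magnitude used for all arithmetic, so converting back and
    forth between commensurable display units never compounds rounding.
    """

    si: float
    unit: Unit

    @property
    def value(self) -> float:
        return self.si / self.unit.scale

    @property
    def signature(self) -> UnitSignature:
        return self.unit.signature

    # -- arithmetic (SI-canonical) ------------------------------------
    def __add__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        if self.signature != other.signature:
            raise DimensionError(
                f"cannot add {self.signature} and {other.signature}"
            )
        return Quantity(self.si + other.si, self.unit)

    def __sub__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        if self.signature != other.signature:
            raise DimensionError(
                f"cannot subtract {other.signature} from {self.signature}"
            )
        return Quantity(self.si - other.si, self.unit)

    def __neg__(self) -> "Quantity":
        return Quantity(-self.si, self.unit)

    def __mul__(self, other):
        if isinstance(other, Quantity):
            sig = self.signature * other.signature
            return Quantity(self.si * other.si, _anonymous_unit(sig))
        if isinstance(other, (int, float)):
            return Quantity(self.si * other, self.unit)
        return NotImplemented

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Quantity):
            sig = self.signature / other.signature
            return Quantity(self.si / other.si, _anonymous_unit(sig))
        if isinstance(other, (int, float)):
            return Quantity(self.si / other, self.unit)
        return NotImplemented

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            sig = DIMENSIONLESS / self.signature
            return Quantity(other / self.si, _anonymous_unit(sig))
        return NotImplemented

    def __pow__(self, power) -> "Quantity":
        sig = self.signature**power
        return Quantity(self.si**power, _anonymous_unit(sig))

    def __abs__(self) -> "Quantity":
        return Quantity(abs(self.si), self.unit)

    def __lt__(self, other: "Quantity") -> bool:
        self._require_same(other, "compare")
        return self.si < other.si

    def __le__(self, other: "Quantity") -> bool:
        self._require_same(other, "compare")
        return self.si <= other.si

    def _require_same(self, other: "Quantity", verb: str) -> None:
        if self.signature != other.signature:
            raise DimensionError(
                f"cannot {verb} {self.signature} with {other.signature}"
            )

    def to(self, target: UnitLike) -> "Quantity":
        return convert(self, target)

    def __repr__(self) -> str:
        return f"Quantity({self.value!r}, {self.unit.name!r})"


def _anonymous_unit(sig: UnitSignature) -> Unit:
    return Unit(sig, 1.0, str(sig))


def quantity(value: float, unit: UnitLike) -> Quantity:
    """Construct a :class:`Quantity` from a magnitude and a unit (string ok)."""
    u = _as_unit(unit)
    return Quantity(float(value) * u.scale, u)


def convert(q: Quantity, target_unit: UnitLike) -> Quantity:
    """Re-express ``q`` in a commensurable display unit.

    The SI magnitude is untouched, so ``convert`` is exactly invertible up
    to the one multiplication performed when reading ``.value``.
    """
    target = _as_unit(target_unit)
    if q.signature != target.signature:
        raise DimensionError(
            f"cannot convert {q.signature} to {target.signature}"
        )
    return Quantity(q.si, target)


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Outcome of one equation-level dimensional check.

    ``residual`` is lhs/rhs: dimensionless iff the equation is consistent.
    """

    passed: bool
    lhs: UnitSignature
    rhs: UnitSignature
    residual: UnitSignature
    context: str = ""

    def __bool__(self) -> bool:
        return self.passed

    def __str__(self) -> str:
        tag = "pass" if self.passed else "FAIL"
        msg = f"[{tag}] {self.context or 'equation'}: {self.lhs} vs {self.rhs}"
        if not self.passed:
            msg += f" (residual {self.residual})"
        return msg


def check_equation(
    lhs_unit: UnitSignature | Unit | str,
    rhs_unit: UnitSignature | Unit | str,
    context: str = "",
) -> ConsistencyVerdict:
    """Compare the unit signatures of an equation's two sides.

    Always returns a verdict object, never raises: the point is to collect
    every inconsistency in a model, not to stop at the first.
    """
    lhs = _as_unit(lhs_unit).signature
    rhs = _as_unit(rhs_unit).signature
    return ConsistencyVerdict(lhs == rhs, lhs, rhs, lhs / rhs, context)


def audit_model_units(graph) -> list[ConsistencyVerdict]:
    """Run the dimensional audit over every equation of an assembled graph.

    ``graph`` must expose ``unit_equations()`` yielding
    ``(context, lhs_signature, rhs_signature)`` triples, which
    :class:`avnode.network.ComponentGraph` generates during assembly.
    Returns one verdict per equation; the audit as a whole passes iff all do.
    """
    if hasattr(graph, "require_assembled"):
        graph.require_assembled()
    return [
        check_equation(lhs, rhs, context)
        for context, lhs, rhs in graph.unit_equations()
    ]
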