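"""Conservation-law calcium handling: compartment, buffer, transport physics.

Intracellular calcium lives in four compartments — cytosol, the "fuzzy"
submembrane subspace, and the junctional and network sarcoplasmic
reticulum (jsr/nsr) — coupled by gradient-driven transport (SR release
through the ryanodine receptor, subspace-to-cytosol diffusion, nsr-to-jsr
transfer) and an active uptake pump (SERCA).  The state variable of a
compartment is the *amount of substance* (mol), not the concentration:
transport moves amount between two sides and conserves it exactly by
construction, while concentrations are derived as n/V at the interface.

Buffers (calmodulin CM, calsequestrin CQ, the troponin sites TC/TMC/TMM,
sarcolemmal SL) bind calcium inside a host compartment with simple
on/off kinetics; the host's calcium balance receives the bound flux with
negative sign.

This module holds the physics; the component wrappers that plug these
pieces into an acausal graph live in :mod:`avnode.network`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .channels import FARADAY
from .quantities import Quantity, parse_unit, quantity

__all__ = [
    "COMPARTMENT_NAMES",
    "BUFFER_NAMES",
    "TRANSPORT_LABELS",
    "CompartmentSpec",
    "BufferSpec",
    "TransportSpec",
    "GaussianStimulus",
    "buffer_rhs",
    "transport_flow",
    "current_to_molar_flow",
    "gaussian_stimulus",
    "michaelis_uptake_rate",
]

COMPARTMENT_NAMES = ("cyto", "sub", "jsr", "nsr")
BUFFER_NAMES = ("CM", "CQ", "TC", "TMC", "TMM", "SL")
#: transport labels: rel (jsr->sub, ryanodine receptor), diff (sub->cyto),
#: tr (nsr->jsr), up (cyto->nsr, SERCA)
TRANSPORT_LABELS = ("rel", "diff", "tr", "up")

_VOLUME = parse_unit("m^3").signature
_CONC = parse_unit("mM").signature
_ON_RATE = parse_unit("1/(mM.s)").signature
_OFF_RATE = parse_unit("1/s").signature
_TIME = parse_unit("s").signature
_AMPERE = parse_unit("A").signature


@dataclass(frozen=True)
class CompartmentSpec:
    """A calcium compartment: fixed volume, variable amount of substance."""

    name: str
    volume: Quantity
    c0: Quantity  # initial concentration

    def __post_init__(self) -> None:
        if self.volume.signature != _VOLUME or self.volume.si <= 0:
            raise ValueError(
                f"compartment {self.name}: volume must be a positive m^3"
            )
        if self.c0.signature != _CONC or self.c0.si < 0:
            raise ValueError(
                f"compartment {self.name}: c0 must be a nonnegative mM"
            )

    @property
    def n0(self) -> Quantity:
        """Initial amount of substance (mol)."""
        return quantity(self.c0.si * self.volume.si, "mol")


@dataclass(frozen=True)
class BufferSpec:
    """A calcium buffer inside a host compartment.

    ``f`` is the occupancy fraction; its kinetics are
    df/dt = kf*c*(1-f) - kb*f, and the host calcium balance receives
    -CT*df/dt (in concentration terms; the amount flux is that times the
    host volume).
    """

    name: str
    total: Quantity  # total site concentration CT
    kf: Quantity  # on-rate, 1/(mM s)
    kb: Quantity  # off-rate, 1/s
    f0: float = 0.0

    def __post_init__(self) -> None:
        if self.total.signature != _CONC or self.total.si < 0:
            raise ValueError(f"buffer {self.name}: total must be a mM >= 0")
        if self.kf.signature != _ON_RATE or self.kf.si < 0:
            raise ValueError(
                f"buffer {self.name}: kf must have signature 1/(mM.s), >= 0"
            )
        if self.kb.signature != _OFF_RATE or self.kb.si < 0:
            raise ValueError(
                f"buffer {self.name}: kb must have signature 1/s, >= 0"
            )
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"buffer {self.name}: f0 outside [0, 1]")


@dataclass(frozen=True)
class TransportSpec:
    """Inactive (gradient-driven) transport between two compartments.

    The molar flow follows the general rule
    Phi = P * min(V_src, V_dst) * (c_src - c_dst); for equal volumes the
    volume factors cancel against the destination's n -> c conversion and
    the familiar simplified printed form P*(c_src - c_dst) re-emerges.
    """

    label: str
    src: str
    dst: str
    rate: Quantity  # 1/s

    def __post_init__(self) -> None:
        if self.rate.signature != _OFF_RATE or self.rate.si < 0:
            raise ValueError(
                f"transport {self.label}: rate must have signature 1/s, >= 0"
            )


def buffer_rhs(b: BufferSpec, f: float, c: Quantity | float) -> Quantity:
    """Occupancy derivative df/dt = kf*c*(1-f) - kb*f, in 1/s."""
    c_si = c.si if isinstance(c, Quantity) else float(c)
    return quantity(b.kf.si * c_si * (1.0 - f) - b.kb.si * f, "1/s")


def transport_flow(
    t: TransportSpec,
    v_src: Quantity,
    v_dst: Quantity,
    c_src: Quantity | float,
    c_dst: Quantity | float,
) -> Quantity:
    """Molar flow Phi = P*min(V_src, V_dst)*(c_src - c_dst), in mol/s.

    The same Phi leaves the source and enters the destination, so
    dn_src/dt + dn_dst/dt = 0 exactly.
    """
    cs = c_src.si if isinstance(c_src, Quantity) else float(c_src)
    cd = c_dst.si if isinstance(c_dst, Quantity) else float(c_dst)
    vmin = min(v_src.si, v_dst.si)
    return quantity(t.rate.si * vmin * (cs - cd), "mol/s")


def current_to_molar_flow(i: Quantity | float, z: int) -> Quantity:
    """Molar flow delivered to the intracellular side by an ionic current.

    Outward-positive current convention: Phi = -i/(z*F), so an inward
    (negative) calcium current (z = 2) adds calcium to the cell.
    """
    if z == 0:
        raise ValueError("valence z must be nonzero")
    i_si = i.si if isinstance(i, Quantity) else float(i)
    return quantity(-i_si / (z * FARADAY), "mol/s")


@dataclass(frozen=True)
class GaussianStimulus:
    """Sum-of-Gaussians dummy current for isolating the calcium subsystem.

    Emulates the time course of the calcium-carrying membrane currents
    during an action potential with physiologically plausible shape, so the
    calcium handling can be exercised without any feedback loop.
    Components are (amplitude A, center mu, width sigma) triples.
    """

    components: Sequence[tuple[Quantity, Quantity, Quantity]]

    def __post_init__(self) -> None:
        for amp, mu, sigma in self.components:
            if amp.signature != _AMPERE:
                raise ValueError("stimulus amplitude must be in amperes")
            if mu.signature != _TIME or sigma.signature != _TIME:
                raise ValueError("stimulus center/width must be in seconds")
            if sigma.si <= 0:
                raise ValueError("stimulus width must be positive")

    def current_si(self, t: float) -> float:
        return sum(
            amp.si * math.exp(-((t - mu.si) ** 2) / (2.0 * sigma.si**2))
            for amp, mu, sigma in self.components
        )


def gaussian_stimulus(s: GaussianStimulus, t: Quantity | float) -> Quantity:
    """Evaluate the stimulus current sum_j A_j exp(-(t-mu_j)^2 / 2 sigma_j^2)."""
    t_si = t.si if isinstance(t, Quantity) else float(t)
    return quantity(s.current_si(t_si), "A")


def michaelis_uptake_rate(
    c: float, v_max: float, k_m: float
) -> float:
    """Default saturating SERCA-style uptake rate (mol/s), SI floats.

    A plain Michaelis-type law v_max*c/(c + k_m); the original pump's rate
    law is not part of this kit's sources, so these parameters must come
    from user configuration and the default is explicitly a non-reference
    placeholder.
    """
    if k_m <= 0:
        raise ValueError("k_m must be positive")
    return v_max * c / (c + k_m)
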