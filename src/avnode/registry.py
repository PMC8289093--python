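"""Machine-readable parameter, correction, and composition ledger.

The original AV-node cell family (atrionodal AN, nodal N, and nodal-His NH
cells) was published with a sizeable number of discrepancies between the
article, its C++ code, and the derived CellML model: undocumented parameter
changes, digit transpositions, sign errors, and missed ms/s conversions.
This module ships that bookkeeping as structured data
(``data/registry.yaml``) with provenance-aware lookup, so model code never
hard-codes a silently "fixed" number.

A deliberate design point: where the record does not identify which source
erred (e.g. the troponin-Mg on-rate kfTMC, or the cell volume V_cell),
``lookup(..., source="corrected")`` raises :class:`AmbiguousValueError`
instead of guessing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .quantities import Quantity, quantity

__all__ = [
    "ParameterRecord",
    "CorrectionEntry",
    "CellFamilyManifest",
    "Registry",
    "UnknownParameterError",
    "AmbiguousValueError",
    "load_registry",
    "lookup",
    "corrections_for",
    "composition_manifest",
]

SOURCES = ("article", "cpp", "cellml", "corrected")
CELL_TYPES = ("AN", "N", "NH", "shared")


class UnknownParameterError(KeyError):
    """No record matches the requested name/cell-type/source."""


class AmbiguousValueError(ValueError):
    """The ledger leaves the canonical ("corrected") choice open."""


@dataclass(frozen=True)
class ParameterRecord:
    """One named parameter with per-source values and a provenance note."""

    name: str
    component: str
    cell_types: tuple[str, ...]
    unit: str
    values: dict[str, float]
    corrected: float | str | None
    provenance: str

    def value(self, source: str) -> Quantity:
        if source == "corrected":
            if self.corrected == "ambiguous":
                raise AmbiguousValueError(
                    f"{self.name} ({'/'.join(self.cell_types)}): no canonical "
                    f"value; sources disagree: {self.values}"
                )
            if self.corrected is None:
                raise UnknownParameterError(
                    f"{self.name}: no corrected value recorded"
                )
            return quantity(self.corrected, self.unit)
        if source not in self.values:
            raise UnknownParameterError(
                f"{self.name}: no value for source {source!r} "
                f"(have {sorted(self.values)})"
            )
        return quantity(self.values[source], self.unit)


@dataclass(frozen=True)
class CorrectionEntry:
    """One ledger entry for an error or gap in the published equations."""

    component: str
    location: str
    kind: str  # sign | scale | typo | missing
    description: str
    factor: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "scale" and self.factor is None:
            raise ValueError("scale corrections must carry an exact factor")


@dataclass(frozen=True)
class CellFamilyManifest:
    """Packaged composition of the AN/N/NH cell family."""

    channels: dict[str, tuple[str, ...]]  # cell type -> channel components
    pumps: tuple[str, ...]
    compartments: tuple[str, ...]
    fixed_concentrations: tuple[str, ...]

    @property
    def channel_types(self) -> frozenset[str]:
        return frozenset(c for chans in self.channels.values() for c in chans)


@dataclass
class Registry:
    records: list[ParameterRecord]
    corrections: list[CorrectionEntry]
    manifest: CellFamilyManifest
    _index: dict[tuple[str, str], ParameterRecord] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        for rec in self.records:
            for ct in rec.cell_types:
                self._index[(rec.name, ct)] = rec

    def lookup(
        self, name: str, cell_type: str = "shared", source: str = "corrected"
    ) -> Quantity:
        """Return the requested source's value with its unit.

        A cell-type-specific lookup falls back to a shared record, so e.g.
        the buffer rates (recorded once) resolve for any cell type.
        """
        if source not in SOURCES:
            raise UnknownParameterError(
                f"unknown source {source!r}; expected one of {SOURCES}"
            )
        rec = self._index.get((name, cell_type)) or self._index.get(
            (name, "shared")
        )
        if rec is None:
            known = sorted({n for n, _ in self._index})
            raise UnknownParameterError(
                f"unknown parameter {name!r} for cell type {cell_type!r}; "
                f"known parameters: {known}"
            )
        return rec.value(source)

    def corrections_for(self, component: str) -> list[CorrectionEntry]:
        """All ledger entries for a component, in ledger order (maybe empty)."""
        return [c for c in self.corrections if c.component == component]

    def composition_manifest(self) -> CellFamilyManifest:
        return self.manifest

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": r.name,
                    "component": r.component,
                    "cell_types": list(r.cell_types),
                    "unit": r.unit,
                    "values": dict(r.values),
                    "corrected": r.corrected,
                    "provenance": r.provenance,
                }
                for r in self.records
            ],
            "corrections": [
                {
                    "component": c.component,
                    "location": c.location,
                    "kind": c.kind,
                    "description": c.description,
                    **({"factor": c.factor} if c.factor is not None else {}),
                }
                for c in self.corrections
            ],
            "composition": {
                "channels_shared": list(self.manifest.channels["AN"]),
                "channels_extra": {
                    ct: sorted(
                        set(chans) - set(self.manifest.channels["AN"])
                    )
                    for ct, chans in self.manifest.channels.items()
                    if set(chans) - set(self.manifest.channels["AN"])
                },
                "pumps": list(self.manifest.pumps),
                "compartments": list(self.manifest.compartments),
                "fixed_concentrations": list(
                    self.manifest.fixed_concentrations
                ),
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )

    @classmethod
    def from_dict(cls, data: dict) -> "Registry":
        records = [
            ParameterRecord(
                name=p["name"],
                component=p["component"],
                cell_types=tuple(p["cell_types"]),
                unit=str(p["unit"]),
                values={k: float(v) for k, v in p["values"].items()},
                corrected=p.get("corrected"),
                provenance=str(p.get("provenance", "")).strip(),
            )
            for p in data["parameters"]
        ]
        corrections = [
            CorrectionEntry(
                component=c["component"],
                location=str(c["location"]).strip(),
                kind=c["kind"],
                description=str(c["description"]).strip(),
                factor=float(c["factor"]) if "factor" in c else None,
            )
            for c in data["corrections"]
        ]
        comp = data["composition"]
        shared = tuple(comp["channels_shared"])
        extra = comp.get("channels_extra", {})
        channels = {
            ct: shared + tuple(extra.get(ct, ())) for ct in ("AN", "N", "NH")
        }
        manifest = CellFamilyManifest(
            channels=channels,
            pumps=tuple(comp["pumps"]),
            compartments=tuple(comp["compartments"]),
            fixed_concentrations=tuple(comp.get("fixed_concentrations", ())),
        )
        return cls(records, corrections, manifest)

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_DEFAULT: Registry | None = None


def load_registry() -> Registry:
    """Load (and cache) the registry shipped with the package."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = importlib.resources.files("avnode").joinpath(
            "data/registry.yaml"
        )
        _DEFAULT = Registry.from_dict(yaml.safe_load(ref.read_text()))
    return _DEFAULT


def lookup(
    name: str, cell_type: str = "shared", source: str = "corrected"
) -> Quantity:
    return load_registry().lookup(name, cell_type, source)


def corrections_for(component: str) -> list[CorrectionEntry]:
    return load_registry().corrections_for(component)


def composition_manifest() -> CellFamilyManifest:
    return load_registry().composition_manifest()
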