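"""Provenance-aware parameter lookup and the corrections ledger.

The three published sources (article, C++ code, CellML model) disagree on
several parameters; the registry stores every source's value and refuses
to guess where no canonical choice exists.
"""

from avnode.registry import (
    AmbiguousValueError,
    composition_manifest,
    corrections_for,
    lookup,
)

# the SR release rate: the article says 5000/s, both code bases 1500/s
# for the N cell — the corrected lookup returns the code value
for source in ("article", "cpp", "cellml", "corrected"):
    q = lookup("P_rel", "N", source)
    print(f"P_rel (N cell, {source:9}): {q.value:g} 1/s")

# where the record is genuinely ambiguous, lookup refuses
try:
    lookup("kfTMC", "shared", "corrected")
except AmbiguousValueError as err:
    print(f"\nkfTMC corrected -> refused: {err}")

print("\ncorrections logged for the transient outward channel:")
for entry in corrections_for("I_to"):
    print(f"  [{entry.kind}] {entry.location}: {entry.description}")

m = composition_manifest()
print(
    f"\ncell family composition: {len(m.channel_types)} ion channel types, "
    f"{len(m.pumps)} pumps, {len(m.compartments)} calcium compartments"
)
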