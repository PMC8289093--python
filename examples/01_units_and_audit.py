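"""Unit signatures, conversions, and the model-wide dimensional audit.

Builds a tiny clamped-channel circuit, deliberately breaks one parameter's
unit, and shows how the audit pinpoints the inconsistent equation.
"""

from avnode.presets import build_gate_relaxation
from avnode.quantities import audit_model_units, check_equation, convert, quantity

# the classic ms^-1 -> s^-1 correction: an on-rate printed as 0.534 per
# (mM ms) is really 534 per (mM s)
kf = quantity(0.534, "1/(mM.ms)")
print(f"0.534 1/(mM.ms) = {convert(kf, '1/(mM.s)').value:g} 1/(mM.s)")

# equation-level check: Ohm's law is dimensionally sound, a stray square
# of the voltage is not
print(check_equation("A", "S.V"))
print(check_equation("A", "S.V^2"))

graph = build_gate_relaxation()
graph.assemble()
verdicts = audit_model_units(graph)
print(f"\nshipped demo model: {sum(v.passed for v in verdicts)}/{len(verdicts)} "
      "equations dimensionally consistent")

# break a parameter on purpose: give the conductance volt units
graph.components["ch"].channel.g_max = quantity(1.0, "V")
graph.assemble()
for v in audit_model_units(graph):
    if not v.passed:
        print("flagged:", v)
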