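"""Electric-analog and GHK channel currents.

Shows the gated-conductance current with the printed sustained-inward
constants, the sodium open-ratio algebra, and the GHK flux equation's
behavior around its removable singularity at 0 mV.
"""

from avnode.channels import electric_current, ghk_current, sodium_open_ratio
from avnode.presets import sodium_channel, sustained_inward_channel
from avnode.quantities import quantity

ist = sustained_inward_channel()
i = electric_current(ist, quantity(0.0, "V"), {"act": 1.0, "inact": 1.0})
print(f"sustained inward channel, fully open at 0 mV: i = {i.si*1e12:.2f} pA")
print("  (g_max 0.1 nS times the 37.4 mV driving force; outward positive)\n")

print("sodium open ratio act^3 * (0.635 fast + 0.365 slow):")
for act, fast, slow in [(1, 1, 1), (0.5, 1.0, 0.0)]:
    print(f"  act={act}, fast={fast}, slow={slow} -> "
          f"{sodium_open_ratio(act, fast, slow):.6f}")

na = sodium_channel()
print(f"\nGHK sodium channel (z=1, {na.c_in.value:g}/{na.c_out.value:g} mM in/out):")
print(f"  Nernst potential: {na.nernst_potential.si*1e3:+.1f} mV "
      f"(current crosses zero there)")
open_gates = {"act": 1.0, "inact_fast": 1.0, "inact_slow": 1.0}
for mv in (-1e-5, 0.0, 1e-5):
    i = ghk_current(na, quantity(mv * 1e-3, "V"), open_gates)
    print(f"  i({mv:+.0e} mV) = {i.si*1e12:.6f} pA")
print("  -> continuous through 0 mV: the avoidable discontinuity is "
      "patched by a Taylor expansion")
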