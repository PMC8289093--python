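"""Four-state Na+/Ca2+ exchanger: steady-state occupancies and current.

The steady state of the four-state cycle has a closed form (cubic
polynomials in the eight rates); only the 1<->2 transition is
electrogenic, so the current is the net flux on that single edge.
"""

from avnode.exchanger import (
    FourStateRates,
    naca_current,
    state_fractions,
    x_terms,
)
from avnode.presets import demo_exchanger_rates
from avnode.quantities import quantity

k = demo_exchanger_rates()
x = x_terms(k)
E = state_fractions(x)
print("steady-state occupancies E1..E4:",
      " ".join(f"{e:.4f}" for e in E.as_tuple()))
print(f"(sum = {sum(E.as_tuple()):.15f})")

amp = quantity(0.5e-9, "A")  # within the published 0.25..1 nA bracket
i = naca_current(k, amp)
print(f"exchanger current at k_NaCa = 0.5 nA: {i.si*1e12:.3f} pA")

# detailed balance: equalize the forward/backward cycle products and the
# current vanishes identically
kb = FourStateRates(
    k12=k.k12, k21=k.k21, k23=k.k23, k32=k.k32, k34=k.k34, k43=k.k43,
    k14=(k.k12 * k.k23 * k.k34 * k.k41) / (k.k21 * k.k32 * k.k43),
    k41=k.k41,
)
print(f"cycle-balanced rates: current = {naca_current(kb, amp).si:.2e} A "
      "(zero net flux on the electrogenic edge)")
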