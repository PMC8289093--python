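# avnode

A modular cell-electrophysiology modeling kit for the atrioventricular
(AV) node cell family — atrionodal (AN), nodal (N), and nodal-His (NH)
cells — built the way well-engineered simulation software is built:
small acausal components with automatic conservation laws, pervasive
unit checking, a provenance-aware parameter registry, and a
deterministic regression harness.

It is aimed at cardiac modelers who want to reuse or extend AV-node
channel and calcium-handling components without re-deriving them from a
tangle of supplements, and at model engineers interested in applying
software-engineering practice (unit tests, regression tests, dimensional
audits) to electrophysiological ODE models.

## The models at the core

- **Hodgkin–Huxley gates.** A gate tracks the open fraction n of a
  channel's gating structure, dn/dt = (n∞(v) − n)/τ(v), with α/β rate
  form supported via n∞ = α/(α+β), τ = 1/(α+β). Steady states and time
  constants are generalized-logistic fits
  y(v) = y_min + (y_max − y_min)/(1 + e^(−sx(v−x0))).
- **Electric-analog channels.** i = open_ratio · g_max · (v − v_eq),
  outward-positive, with the open ratio an algebra over gate states
  (e.g. the sodium channel's act³·(0.635·fast + 0.365·slow)).
- **GHK flux.** The sodium current follows the Goldman–Hodgkin–Katz
  equation i = P·A·zF·(c_in − c_out e^(−u))·u/(1−e^(−u)), u = zvF/RT,
  with its removable singularity at 0 mV patched by a Taylor expansion.
- **Na⁺/Ca²⁺ exchanger.** The four-state cycle's analytic steady state:
  occupancies from cubic polynomials x₁..x₄ in the eight rates, current
  I = k_NaCa(k21·x2 − k12·x1)/Σxᵢ on the single electrogenic edge.
- **Calcium handling.** Four compartments (cytosol, subspace, junctional
  and network SR) whose states are amounts of substance, coupled by
  gradient transport Φ = P·min(V_src,V_dst)·(c_src − c_dst), buffers
  df/dt = kf·c(1−f) − kb·f, RyR release, and SERCA uptake — conservation
  of calcium holds by construction.
- **Acausal networks.** Components connect through electrical pins and
  chemical ports; Kirchhoff's current law and conservation of mass are
  generated automatically, so the same channel works under voltage-clamp
  and current-clamp drives. Systems integrate with a stiff variable-order
  BDF method.

Only the handful of published parameterizations ship as reference values
(see `docs/methods.md`); demonstration gate fits are labeled synthetic.
The registry separates article/C++/CellML values and refuses to guess
where no canonical choice exists.

## Worked example

Evaluate the published sodium fast-inactivation time-constant fit and
relax a gate under clamp (`examples/03_hh_gate.py`):

```text
tau_inact_fast(  +100 mV) =    0.350 ms
tau_inact_fast(   -40 mV) =   15.350 ms
tau_inact_fast(  -200 mV) =   30.350 ms
-> declining sigmoid: 0.35 ms floor when depolarized, 30.35 ms ceiling
   when hyperpolarized, midpoint at -40 mV

clamped at -20 mV: n relaxes to n_inf = 0.7773 with tau = 8.0 ms
max deviation from the exponential closed form over 5 tau: 6.51e-10
```

The three tau values are the fit's two asymptotes and midpoint: strongly
depolarized membranes inactivate fast (0.35 ms), strongly hyperpolarized
ones slowly (30.35 ms), and the transition is steepest at −40 mV. The
last line verifies the integrated gate against its exponential solution.

Query the parameter registry (`examples/02_registry.py`):

```text
P_rel (N cell, article  ): 5000 1/s
P_rel (N cell, cpp      ): 1500 1/s
P_rel (N cell, cellml   ): 1500 1/s
P_rel (N cell, corrected): 1500 1/s

kfTMC corrected -> refused: kfTMC (shared): no canonical value; sources
disagree: {'article': 227700.0, 'cpp': 222700.0, 'cellml': 227700.0}
```

The SR release rate differs between the article and both code bases; the
corrected lookup returns the code value. For kfTMC no source is
identifiably right, so the registry raises instead of guessing.

Each script in `examples/` is a short, self-contained narrative:
units/audit, registry, gates, channels, exchanger, calcium, I–V
protocols, and the regression harness. A thin CLI wraps the harness:

```sh
avnode list
avnode run gate_relaxation --out out/
avnode check-units demo_cell_an
avnode registry --component Ca_handling
```

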