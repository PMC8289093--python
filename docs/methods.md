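# Methods

`avnode` is a modeling kit for the rabbit atrioventricular-node cell family
(atrionodal AN, nodal N, and nodal-His NH cells): composable
Hodgkin–Huxley gates, electric-analog and Goldman–Hodgkin–Katz (GHK) ion
channels, the four-state Na⁺/Ca²⁺ exchanger, conservation-law calcium
handling, acausal component graphs compiled to stiff ODE systems,
clamp-experiment protocols, and a regression/unit-consistency harness.
This note records the model, its assumptions, the numerical choices, and
the limits of what the shipped demonstrations show.

## Scope and what is reference vs. synthetic

The original cell family was published with most per-channel rate
equations and parameters in a supplement that is not part of this kit's
sources. The kit therefore ships the *structure* — channel base classes,
gate primitives, calcium compartments, the composition manifest — with
pluggable rate-law slots, and only the handful of printed
parameterizations as reference values:

- the sustained-inward channel constants (g_max = 0.1 nS,
  v_eq = −37.4 mV);
- the sodium fast/slow inactivation time-constant fits
  (fast: 0.35 ms floor, 30.35 ms ceiling, inflection −40 mV,
  steepness −1000/6 V⁻¹; slow: 2.95 ms floor, 122.95 ms ceiling,
  inflection −60 mV, steepness −1000/2 V⁻¹);
- the sodium open-ratio algebra act³·(0.635·fast + 0.365·slow);
- the registry values (see below): P_rel, V_cell, C_m, kfTC, kfTMC, E_st;
- protocol settings (current pulses: T_hold 300 ms, T_pulse 1 ms,
  I_pulse −1.2 nA; solver defaults 0–2.5 s, tolerance 1e-12,
  output interval 1e-4 s).

Every other number in `presets.py` (steady-state fits, activation rates,
permeabilities, concentrations, sub-compartment volume fractions, buffer
and SERCA parameters, exchanger rates) is a clearly labeled SYNTHETIC
placeholder chosen for physiological plausibility and numerical good
behavior. The demo cell is a *reduced demonstration*, not a reproduction
of the published action potentials; the kit's tests verify structure,
conservation laws, closed forms, and the printed anchors, and say nothing
about agreement with the original cell's electrophysiology. The
acetylcholine-sensitive current is out of scope (no published reference
for its equations exists).

## Quantities and unit audit

All values are `Quantity` objects: a float stored canonically in strict
SI, tagged with a signature of exponents over the seven SI base
dimensions (rational exponents allowed; shipped components use integers).
Display units cover the cardiac dialect (mV, nA, pA, nS, pF, mM, ms, nl,
pl) with a plain-text grammar (`.` product, `/` division, `^` power, e.g.
`1/(mM.s)`). Conversions rescale exactly by the ratio of unit scales; the
SI magnitude is never touched, so round trips do not compound rounding.

Assembly generates one unit equation per model equation — channel
currents, gate derivatives, buffer kinetics, transport flows, capacitor
law, and every term of every node balance — each carrying the signatures
of the *actual configured parameters*, so a conductance accidentally
supplied in volts is flagged at the specific equation. `check_equation`
returns verdict objects rather than raising: an audit collects every
inconsistency in one pass. Experiments refuse to simulate while any
verdict fails.

Temperature is a fixed model parameter (default 310 K); affine units
(°C) are unsupported because temperature only ever enters through RT/F.

## Parameter registry

`data/registry.yaml` records, per parameter, the value printed in the
article and the values used by the original C++ and CellML codes, plus a
`corrected` entry where exactly one choice is defensible:

- P_rel: both code bases agree (1805.6 s⁻¹ AN/NH, 1500.0 s⁻¹ N) against
  the printed 5000 s⁻¹; the code value is corrected.
- C_m: CellML swaps the N and NH values; article/C++ agree and are
  corrected (N 2.9e-11 F, AN/NH 4.0e-11 F).
- kfTC: 534 ↔ 543 is a digit transposition in CellML; 534 1/(mM·s) is
  corrected.
- kfTMC (227700 vs 222700) and V_cell (article vs two slightly different
  code values): no source is identifiably right, so a `corrected` lookup
  raises an explicit "ambiguous" error rather than guessing.
- E_st: the sign depends on the equation convention; under this kit's
  outward-positive electric analog i = open_ratio·g_max·(v − v_eq) the
  consistent value is −37.4 mV, which the shipped component uses; the
  registry stores all three source values and the convention note.

Corrections (sign errors, scale errors with exact factors, missing
information) are first-class entries; each ms↔s scale entry's factor is
tested to equal the exact unit-conversion factor. Quantities whose value
is not printed anywhere in the kit's sources (SL_tot, P_Na, [ACh]_i,
ach_l) are recorded as `missing` notes without numbers.

The composition manifest records the family's eight ion-channel types,
two pumps (Na⁺/Ca²⁺ exchanger, Na⁺/K⁺ pump), and four variable-calcium
compartments. The per-cell split beyond that is not printed; the manifest
assigns the seven shared channels to all three cell types and the
sustained-inward channel to the N cell only.

## Gates and fitting functions

A gate is first-order in the open fraction n. The steady/time-constant
form integrates dn/dt = (n∞(v) − n)/τ(v); the rate form
dn/dt = α(v)(1 − n) − β(v)n maps onto it by n∞ = α/(α+β), τ = 1/(α+β)
(an algebraic identity, property-tested to 1e-12). Fitting-function slots
are plain callables (SI volts in, SI value out) tagged with output unit
signatures so the audit covers user-supplied fits.

The generalized logistic is

    y(v) = y_min + (y_max − y_min) / (1 + exp(−sx·(v − x0)))

the unique standard logistic consistent with all quoted properties of the
published fits (midpoint at x0, asymptotes y_min/y_max, direction from
the sign of sx). The exponent argument is clamped at ±700: beyond that
the asymptote is exact in double precision anyway. Note the quantitative
fine print: at +100 mV the fast-inactivation τ is within 1e-8 (not
1e-15) of its 0.35 ms floor — the residual exp term is ~7e-11 of the
30 ms span — and a gate started far from equilibrium needs ~14τ, not
10τ, to come within 1e-6 of n∞ (e⁻¹⁰ ≈ 4.5e-5).

## Channels

Electric-analog channels compute i = open_ratio·g_max·(v − v_eq),
outward-positive, with the open ratio a validated composition over gate
states (powers ≥ 1, convex sums; config strings like
`"act^3 * (0.635*fast + 0.365*slow)"` are parsed through a whitelisted
AST — no general evaluation).

The GHK channel stores permeability×area as one configured quantity with
signature m³/s, which is the dimensional contract that makes
(m³/s)·(C/mol)·(mol/m³) come out in amperes; the published permeability
unit confusion (nl/s printed where a per-area permeability is meant) is
exactly the failure mode this contract removes. The current is

    i = P·A · z·F · (c_in − c_out·e^(−u)) · u/(1 − e^(−u)),  u = zvF/RT

with the removable singularity at u = 0 patched by the second-order
Taylor expansion of u/(1 − e^(−u)) for |u| < 1e-4 (relative error
< 1e-9 at the switch point; continuity is unit-tested at ε = 1e-4, 1e-6,
1e-8). This limit-patch policy applies to every rate expression with an
avoidable discontinuity. Constants: F = 96485.33212 C/mol,
R = 8.31446261815324 J/(mol·K) (CODATA).

## Exchanger

The four-state cycle's steady state is the printed closed form: x₁..x₄
are cubic polynomials in the eight rates, normalized to occupancies
E₁..E₄, and the current is k_NaCa·(k21·x2 − k12·x1)/Σx — the net flux on
the single electrogenic 1↔2 edge. Tests verify the polynomials against
an independent oracle (the null space of the master-equation generator,
1000 random rate sets, 1e-9) and that thermodynamically cycle-balanced
rates carry zero current. Note one algebraic fact the tests encode: a
common rescale of all eight rates leaves E₁..E₄ unchanged but scales the
current linearly (the numerator is quartic in the rates, the denominator
cubic). Rate dependence on voltage and ion concentrations is a pluggable
provider slot; the component is deliberately not subdivided, since the
analytic steady state cannot be reassembled from per-edge parts.
k_NaCa carries amperes; densities in pA/pF are converted by multiplying
with C_m before configuration.

## Calcium handling

Compartment states are amounts of substance (mol), not concentrations:
transport components move amount between two sides, so conservation is
exact by construction, and concentration c = n/V is derived at the
chemical interface. Gradient transport follows the general rule
Φ = P·min(V_src, V_dst)·(c_src − c_dst), reconstructed from the printed
special case in which the destination volume cancels (equal volumes give
the familiar dc/dt = P·Δc). Buffers evolve df/dt = kf·c·(1−f) − kb·f and
feed −CT·V_host·df/dt into the host's amount balance (the corrected
negative sign). Channel-to-compartment coupling converts outward current
to molar flow by Φ = −i/(zF).

RyR release is a transport link with constant P_rel plus an optional
modulation hook; SERCA uptake is an active slot with a default
Michaelis-type law v_max·c/(c + k_m) whose parameters are explicitly
non-reference. Sum-of-Gaussians dummy currents emulate the
calcium-carrying membrane currents so the subsystem can be exercised
in isolation; they have plausible shape but no quantitative standing.

## Network assembly and simulation

Components expose electrical pins (potential/current) and chemical ports
(concentration/molar flow); `connect` merges same-kind connectors
(pin↔port is a type error) into nodes via union-find. Assembly:

- exactly one ground per connected electrical subgraph fixes the
  extracellular reference; node potentials are propagated breadth-first
  through potential-defining elements (voltage sources, capacitors whose
  state is the membrane potential v_n − v_p). Unreached nodes raise a
  floating-subgraph error naming a member component; a defining element
  whose both ends are already determined is rejected (its current would
  be indeterminate) — general DAE index reduction is out of scope.
- each chemical node needs exactly one concentration definer (a
  compartment or a fixed-concentration boundary).
- the state vector (gate fractions, buffer occupancies, compartment
  amounts, membrane potentials) is ordered lexicographically by dotted
  component path — determinism requires a rule and none is prescribed.
- Kirchhoff balances are embedded: a capacitor's current is minus the sum
  of the other currents at its node, so node sums are zero to the last
  bit; `node_balances` exposes every signed term for verification.

Integration uses SciPy's variable-order BDF (the open stiff-multistep
equivalent of DASSL), with the published experiment annotation as the
default settings (0–2.5 s, tolerance 1e-12 applied as rtol with a
separately configurable atol, output every 1e-4 s). Piecewise-constant
protocol drives advertise their step times and the horizon is integrated
segment-by-segment between them, so no pulse is stepped over. Output
columns are dotted variable paths filtered by a full-match regular
expression. Compartment amounts are O(1e-16 mol), so calcium experiments
set atol ≈ 1e-28–1e-30; the relevant accuracy control is rtol.

`initialize_steady` relaxes the system under its holding drives —
mirroring the observation that the original initial states resemble the
near-steady state before a pulse — and flags non-convergence by the
scaled residual max|rhs|·t_relax/max(|y|,1) > 1e-3 (a gate relaxed for
10τ sits at ~4e-4); oscillating systems keep their last state and report
non-convergence.

## Protocols

Test-pulse cycles put the pulse in the final T_pulse of each
(T_hold + T_pulse) period. The swept variable defaults to the pulse
potential — experiment tables fix V_hold per experiment — with
`sweep_variable="hold"` available since the prose description reads
either way. "Maximum current" defaults to the signed extremum of largest
magnitude within the pulse window; plain max/min and full-cycle windows
are options, not guesses. Sweeps run ascending and are independently
re-initialized (relax at hold for T_hold) by default; `sequential` mode
carries state across cycles to reproduce the incomplete-recovery
artifact of a too-short T_hold, which matters because slow gates need
tens of seconds to settle.

## Experiments and regression harness

An experiment names a model preset, parameter overrides (dotted
attribute paths with unit-tagged values), solver settings, and a
variable filter. Runs always audit units first. CSV output is
deterministic (comma separator, `.` decimal, a leading `time` column,
shortest-roundtrip float repr; reading uses round-trip float parsing),
so repeated runs are byte-identical and stored references are exact
regression oracles. Default comparison tolerance is relative 1e-6 with
absolute floor 1e-12 per variable; column sets must match exactly and
time grids must agree (interpolating comparison behind a flag).
`update_references` runs everything first, touches nothing on failure,
replaces files atomically, and prints a change summary. A thin CLI
(`avnode list|run|compare|update-refs|check-units|registry`) exposes the
harness with 0/1 exit codes.

Shipped demo experiments use short horizons (0.05–10 s) and tolerances
of 1e-8–1e-10: sizes chosen so the whole suite runs routinely on a
single CPU while still exercising every conservation law and closed
form; the full published defaults remain available by simply not
overriding them.

## Known limitations

- The demo cell does not produce the published action potentials — its
  channel fits are synthetic and the full channel complement (L-type
  calcium, delayed/inward rectifiers, transient outward,
  hyperpolarization-activated, Na⁺/K⁺ pump) ships as configurable
  skeletons without reference parameterizations.
- Only node-balance algebraic structure is supported: no general DAE
  constraints, no event handling beyond piecewise-constant drives, no
  symbolic index reduction.
- The exchanger's voltage/concentration rate laws and the exact RyR/SERCA
  laws must be supplied by the user.
- Buffer occupancies and gate fractions are kept in [0,1] by the
  dynamics, not by clamping; property tests allow 1e-9 solver slack.
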