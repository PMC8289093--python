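# Parameter provenance and corrections ledger for the AV-node cell family.
#
# Each parameter record carries per-source values (article / cpp / cellml) plus,
# where one value is identifiable as the consistent one, a "corrected" entry.
# Where the canonical choice is genuinely open, corrected is the literal string
# "ambiguous" and lookup raises instead of guessing.

parameters:
  - name: P_rel
    component: Ca_handling
    cell_types: [AN, NH]
    unit: "1/s"
    values:
      article: 5000.0
      cpp: 1805.6
      cellml: 1805.6
    corrected: 1805.6
    provenance: >
      SR release rate constant. The article value appears to be an undocumented
      change with a large qualitative effect on simulations; both code bases
      agree on 1805.6 1/s, which is taken as the corrected value.

  - name: P_rel
    component: Ca_handling
    cell_types: [N]
    unit: "1/s"
    values:
      article: 5000.0
      cpp: 1500.0
      cellml: 1500.0
    corrected: 1500.0
    provenance: >
      SR release rate constant for the N cell; both code bases agree on
      1500.0 1/s against the printed 5000 1/s.

  - name: V_cell
    component: Ca_handling
    cell_types: [AN, NH]
    unit: "m^3"
    values:
      article: 3.500e-15
      cpp: 4.398e-15
      cellml: 4.400e-15
    corrected: ambiguous
    provenance: >
      Cell volume. The two code bases disagree with the article and also
      slightly with each other (4.398 vs 4.400 fl); no canonical choice is
      identified, so a corrected lookup is refused as ambiguous.

  - name: V_cell
    component: Ca_handling
    cell_types: [N]
    unit: "m^3"
    values:
      article: 3.500e-15
      cpp: 3.189e-15
      cellml: 3.190e-15
    corrected: ambiguous
    provenance: >
      Cell volume for the N cell; same three-way disagreement as for AN/NH.

  - name: C_m
    component: membrane
    cell_types: [AN]
    unit: F
    values:
      article: 4.0e-11
      cpp: 4.0e-11
      cellml: 4.0e-11
    corrected: 4.0e-11
    provenance: Membrane capacitance; all sources agree for the AN cell.

  - name: C_m
    component: membrane
    cell_types: [N]
    unit: F
    values:
      article: 2.9e-11
      cpp: 2.9e-11
      cellml: 4.0e-11
    corrected: 2.9e-11
    provenance: >
      Membrane capacitance. In the CellML code the N and NH values are
      switched; article and C++ agree on 2.9e-11 F for the N cell.

  - name: C_m
    component: membrane
    cell_types: [NH]
    unit: F
    values:
      article: 4.0e-11
      cpp: 4.0e-11
      cellml: 2.9e-11
    corrected: 4.0e-11
    provenance: >
      Membrane capacitance. CellML carries the N value here by the same swap;
      article and C++ agree on 4.0e-11 F.

  - name: kfTC
    component: Ca_handling
    cell_types: [shared]
    unit: "1/(mM.s)"
    values:
      article: 534.0
      cpp: 534.0
      cellml: 543.0
    corrected: 534.0
    provenance: >
      Troponin-Ca on-rate. The CellML value 543 is a digit transposition;
      article and C++ agree on 534 1/(mM.s).

  - name: kfTMC
    component: Ca_handling
    cell_types: [shared]
    unit: "1/(mM.s)"
    values:
      article: 227700.0
      cpp: 222700.0
      cellml: 227700.0
    corrected: ambiguous
    provenance: >
      Troponin-Mg site Ca on-rate. 227700 vs 222700 looks like a simple typing
      error, but which implementation erred is not established, so a corrected
      lookup is refused as ambiguous.

  - name: E_st
    component: I_st
    cell_types: [N]
    unit: mV
    values:
      article: 37.4
      cpp: 37.4
      cellml: -37.4
    corrected: -37.4
    provenance: >
      Reversal potential of the sustained inward current. The sign depends on
      the equation convention; under this kit's outward-positive electric
      analog i = open_ratio*g_max*(v - v_eq), the consistent value is
      v_eq = -37.4 mV, which is what the shipped I_st component uses.

corrections:
  - component: Ca_handling
    location: "table S12, eq. 5"
    kind: sign
    description: f_CMi and f_TC must have negative sign

  - component: I_NaCa
    location: "table S10, eq. 5"
    kind: sign
    description: Q_n must have positive sign

  - component: I_st
    location: "table S8, eq. 2"
    kind: sign
    description: second occurrence of V must be negative

  - component: Ca_handling
    location: "buffer rate parameters k_x, kb_x (x = f_CM, f_CQ, f_TC, f_TMC, f_TMM)"
    kind: scale
    factor: 1000.0
    description: must be multiplied by 1000 (ms^-1 -> s^-1)

  - component: I_st
    location: "variables tau_qa, tau_qi"
    kind: scale
    factor: 1.0e-3
    description: must be divided by 1000 (ms -> s)

  - component: I_to
    location: "variable tau_q_fast"
    kind: scale
    factor: 0.1
    description: constant 0.1266 must be 0.01266 instead

  - component: I_ACh
    location: all equations
    kind: missing
    description: channel equations exist only in the C++ code; no published reference

  - component: I_ACh
    location: "parameter [ACh]_i"
    kind: missing
    description: not recoverable from any source

  - component: I_Ca_L
    location: parameter ach_l
    kind: missing
    description: not recoverable from any source

  - component: Ca_handling
    location: parameter SL_tot
    kind: missing
    description: >
      sarcolemmal buffer total concentration exists only in the C++ code; no
      numeric value is printed here, so no parameter record is shipped

  - component: Ca_handling
    location: equation for V_cell w.r.t. C_m
    kind: missing
    description: recoverable only from the C++ code

  - component: I_Na
    location: parameter P_Na
    kind: missing
    description: >
      published under the name g_Na with unit nl/s, which is not a permeability
      unit and has the wrong order of magnitude (should be pl/(s.m^2)); the
      numeric value itself is not printed here, so the record stores only this
      correction note

composition:
  channels_shared:
    [I_b, I_Ca_L, I_K_r, I_K_1, I_Na, I_to, I_f]
  channels_extra:
    N: [I_st]
  pumps: [I_NaCa, I_p]
  compartments: [cyto, sub, jsr, nsr]
  fixed_concentrations: [Ca_o, Na_i, Na_o, K_i, K_o]
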