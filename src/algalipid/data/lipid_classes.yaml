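# Polar lipid class catalog for brown-macroalgal lipidomics.
#
# backbone: element counts of the head-group + glycerol scaffold with free
# hydroxyls, so that a species' neutral formula is
#   backbone + sum(acyl free fatty acids) - n_acyl * H2O.
# reported_adducts: the ionisation mode(s) each class is detected in on a
# HILIC ESI platform; the first entry is the class's primary adduct used for
# theoretical catalog generation.
# rt_window: retention-time interval in minutes on the reference HILIC
# gradient, where known.  The isomeric betaine pairs (DGTS/DGTA, MGTS/MGTA)
# share one elemental backbone and are distinguished only by retention time.
# diagnostic_fragments: positive/negative product ions characteristic of the
# head group (m/z, polarity); betaine lipids share the m/z 236.1 head-group
# ion in positive mode.

MGDG:
  n_acyl: 2
  backbone: {C: 9, H: 18, O: 8}
  reported_adducts: ["[M+NH4]+"]
MGMG:
  n_acyl: 1
  backbone: {C: 9, H: 18, O: 8}
  reported_adducts: ["[M+NH4]+"]
DGDG:
  n_acyl: 2
  backbone: {C: 15, H: 28, O: 13}
  reported_adducts: ["[M+NH4]+"]
DGMG:
  n_acyl: 1
  backbone: {C: 15, H: 28, O: 13}
  reported_adducts: ["[M+NH4]+"]
SQDG:
  n_acyl: 2
  backbone: {C: 9, H: 18, O: 10, S: 1}
  reported_adducts: ["[M-H]-"]
SQMG:
  n_acyl: 1
  backbone: {C: 9, H: 18, O: 10, S: 1}
  reported_adducts: ["[M-H]-"]
PC:
  n_acyl: 2
  backbone: {C: 8, H: 20, N: 1, O: 6, P: 1}
  reported_adducts: ["[M+H]+", "[M+CH3COO]-"]
LPC:
  n_acyl: 1
  backbone: {C: 8, H: 20, N: 1, O: 6, P: 1}
  reported_adducts: ["[M+H]+", "[M+CH3COO]-"]
PE:
  n_acyl: 2
  backbone: {C: 5, H: 14, N: 1, O: 6, P: 1}
  reported_adducts: ["[M-H]-", "[M+H]+"]
LPE:
  n_acyl: 1
  backbone: {C: 5, H: 14, N: 1, O: 6, P: 1}
  reported_adducts: ["[M-H]-", "[M+H]+"]
PG:
  n_acyl: 2
  backbone: {C: 6, H: 15, O: 8, P: 1}
  reported_adducts: ["[M-H]-"]
LPG:
  n_acyl: 1
  backbone: {C: 6, H: 15, O: 8, P: 1}
  reported_adducts: ["[M-H]-"]
PI:
  n_acyl: 2
  backbone: {C: 9, H: 19, O: 11, P: 1}
  reported_adducts: ["[M-H]-"]
LPI:
  n_acyl: 1
  backbone: {C: 9, H: 19, O: 11, P: 1}
  reported_adducts: ["[M-H]-"]
DGTS:
  n_acyl: 2
  backbone: {C: 10, H: 21, N: 1, O: 5}
  reported_adducts: ["[M+H]+", "[M+Na]+"]
  rt_window: [4.0, 8.0]
  diagnostic_fragments: [[236.1, positive]]
MGTS:
  n_acyl: 1
  backbone: {C: 10, H: 21, N: 1, O: 5}
  reported_adducts: ["[M+H]+", "[M+Na]+"]
  rt_window: [7.0, 11.0]
  diagnostic_fragments: [[236.1, positive]]
DGTA:
  n_acyl: 2
  backbone: {C: 10, H: 21, N: 1, O: 5}
  reported_adducts: ["[M+H]+", "[M+Na]+"]
  rt_window: [14.0, 18.0]
  diagnostic_fragments: [[236.1, positive]]
MGTA:
  n_acyl: 1
  backbone: {C: 10, H: 21, N: 1, O: 5}
  reported_adducts: ["[M+H]+", "[M+Na]+"]
  rt_window: [25.0, 29.0]
  diagnostic_fragments: [[236.1, positive]]
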