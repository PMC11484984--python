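# Adapted 13-segment coronary diagram for calcium scoring on non-contrast CT.
# Side branches and small distal segments of the standard SCCT diagram are
# collapsed because they cannot be told apart without contrast.
labels:
  - p-RCA
  - m-RCA
  - d-RCA
  - s-RCA
  - LM
  - p-LAD
  - m-LAD
  - d-LAD
  - s-LAD
  - p-LCX
  - m-LCX
  - d-LCX
  - s-LCX

# SCCT segment number/string -> adapted label.
scct_map:
  "1": p-RCA
  "2": m-RCA
  "3": d-RCA
  "4a": d-RCA
  "4b": d-RCA
  "RCA-side": s-RCA
  "5": LM
  "6": p-LAD
  "7": m-LAD
  "8": d-LAD
  "9": s-LAD
  "10": s-LAD
  "17": s-LAD
  "11": p-LCX
  "13": m-LCX
  "15": d-LCX
  "16a": d-LCX
  "16b": d-LCX
  "12": s-LCX
  "14": s-LCX

vessel_map:
  p-RCA: RCA
  m-RCA: RCA
  d-RCA: RCA
  s-RCA: RCA
  LM: LM
  p-LAD: LAD
  m-LAD: LAD
  d-LAD: LAD
  s-LAD: LAD
  p-LCX: LCX
  m-LCX: LCX
  d-LCX: LCX
  s-LCX: LCX

# Adjoining segment pairs (unordered): consecutive segments along each vessel
# plus the left-main bifurcation into p-LAD and p-LCX. Disagreements between
# adjoining segments are down-weighted (0.5) in the weighted kappa.
adjacency:
  - [p-RCA, m-RCA]
  - [m-RCA, d-RCA]
  - [d-RCA, s-RCA]
  - [p-LAD, m-LAD]
  - [m-LAD, d-LAD]
  - [d-LAD, s-LAD]
  - [p-LCX, m-LCX]
  - [m-LCX, d-LCX]
  - [d-LCX, s-LCX]
  - [LM, p-LAD]
  - [LM, p-LCX]
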