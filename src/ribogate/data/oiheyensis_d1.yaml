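# Subdomain registry for the O. iheyensis group II intron domain 1 scaffold.
# Residue ranges use intron (author) numbering on chain A.
name: oiheyensis_d1
chain: A
angle_convention: directed
backbone_atoms: [P, OP1, OP2, "O5'", "C5'", "C4'", "C3'", "O3'"]
subdomains:
  core_D1c:
    - [66, 75]
    - [112, 121]
  peripheral_D1c:
    - [80, 102]
  D1d1:
    - [124, 133]
    - [230, 242]
  i1_i2:
    - [6, 23]
    - [250, 267]
  hinge1:
    - [71, 73]
    - [115, 116]
  # Alternative hinge-1 pairing used for the locking mutagenesis
  # (G114 A115 C116 paired with U71 A72 A73); recorded alongside the
  # 71-73/115-116 definition because the two published variants differ.
  hinge1_methods_variant:
    - [71, 73]
    - [114, 116]
  hinge2:
    - [217, 217]
    - [223, 224]
angles:
  A: [core_D1c, D1d1]
  B: [core_D1c, peripheral_D1c]
  C: [core_D1c, i1_i2]
  D: [D1d1, i1_i2]
gate:
  - [A, 75, "C1'"]
  - [A, 238, "C1'"]
# D1 spans the 5'-terminal ~267 nucleotides; Rg is computed over this range.
rg_ranges:
  - [1, 267]
notes:
  hinge1: >-
    Two hinge-1 definitions are in circulation: 71-73/115-116 (pseudo-torsion
    analysis) and 71-73/114-116 (base-pair locking mutagenesis). Both are
    registered; analyses default to 'hinge1' and should state which was used.
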