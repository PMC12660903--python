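# ribogate

Geometric and kinetic analysis of multidomain ribozyme scaffold dynamics.

Large self-splicing RNAs such as group II introns assemble sequentially: a
5'-terminal scaffold domain (D1, ~270 nt in the *Oceanobacillus iheyensis*
intron) folds first and then gates the docking of the 3'-terminal domains
that bring the active site. Characterising that gating quantitatively means
measuring, across crystal structures, cryo-EM models, and conformational
ensembles: how the scaffold's helical subdomains reorient relative to one
another, which nucleotides move, whether hinge nucleobases flip into or out
of their helix, how far along an opening transition a given conformation
sits, and how mutations in the hinge change splicing kinetics. `ribogate`
implements that toolbox for structural biologists and RNA biophysicists, and
ships synthetic generators so every stage is testable without downloading
coordinates.

## What it computes

* **Scaffold descriptors** — subdomain helical axes by total-least-squares
  line fits to sugar-phosphate backbone atoms; inter-axis *angles A–D*
  between (core D1c, D1d1), (core D1c, peripheral D1c), (core D1c, i1-i2)
  and (D1d1, i1-i2); the *gate distance* d(C1′ G75 – C1′ U238) as a pocket
  aperture proxy; radius of gyration R_g.
* **Superposition and displacement mapping** — closed-form Kabsch alignment
  with iterative outlier rejection, RMSD, and per-residue phosphate
  displacement profiles between two models.
* **Nucleotide conformation** — η/θ pseudo-torsions
  (η = C4′ᵢ₋₁–Pᵢ–C4′ᵢ–Pᵢ₊₁, θ = Pᵢ–C4′ᵢ–Pᵢ₊₁–C4′ᵢ₊₁) and bulged-in /
  bulged-out classification of nucleobases against their helix axis.
* **Path-progress coordinates** — spath and zpath over N milestone
  conformations,
  spath = Σᵢ i·e^(−λR(X−Xᵢ)) / Σᵢ e^(−λR(X−Xᵢ)),
  zpath = −(1/λ)·ln Σᵢ e^(−λR(X−Xᵢ)),
  with milestone paths built from ordered ensembles and λ calibrated as
  2.3 / mean adjacent-milestone distance.
* **Ensemble quantification** — pairwise RMSD matrices, per-frame descriptor
  series, subdomain tip displacements, trend statistics.
* **Splicing kinetics** — the sequential two-step scheme
  P →(k₁) I →(k₂) L with closed-form populations and multi-start
  least-squares fitting; initial-slope + Michaelis–Menten analysis
  (v = v_max·S/(K_M+S)) of spliced-exon-reopening assays, with
  Lineweaver–Burk co-reported; mutant-vs-wild-type activity percentages.

See `docs/methods.md` for models, conventions, and numerical choices.

## Worked example

Build a noisy synthetic four-helix scaffold mimic in the closed-state
geometry, then measure its descriptors:

```sh
$ ribogate synth construct --angle-a 62.9 --gate 32.0 --noise-sigma 0.25 --seed 1 --out closed.pdb
wrote 98 residues; truth angle_A=62.9 deg
$ ribogate descriptors closed.pdb --out closed_descriptors.tsv
angle_A=62.7 deg  gate=32.0 A  rg=26.3 A
```

The TSV holds the full record — the four directed inter-axis angles with
their undirected [0°, 90°] variants, the gate distance, and R_g:

```
model_id  angle_A  angle_B  angle_C  angle_D  gate_distance  rg
closed    62.708   30.123   45.603   59.801   32.000         26.254
```

The construct was built at angle A = 62.9° and gate = 32.0 Å; the measured
62.7° / 32.0 Å shows the fit recovering the construction geometry to a few
tenths of a degree under 0.25 Å coordinate noise.

Fit the two-step splicing scheme to a noisy synthetic time course generated
at k₁ = 0.016 min⁻¹, k₂ = 0.041 min⁻¹ (fraction noise σ = 0.02):

```sh
$ ribogate kinetics fit-splicing tc.tsv --out fit.json
k1=0.0162 min^-1  k2=0.0399 min^-1
```

Both rate constants come back within one standard error of the generating
values (k₁ = 0.0162 ± 0.0003, k₂ = 0.0399 ± 0.0015 min⁻¹), i.e. the first
splicing step is ~2.5-fold slower than the second.

Other stages: `ribogate displace` (per-residue displacement profile),
`ribogate torsions`, `ribogate flipstate`, `ribogate pathcv`,
`ribogate ensemble`, `ribogate synth helix|morph`. Every command writes its
outputs plus a `manifest.json` (inputs, parameters, config hash, version)
for provenance; the same inputs and seed always give identical outputs.

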