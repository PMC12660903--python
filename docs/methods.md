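# Methods

`ribogate` quantifies how the helical subdomains of a large multidomain
ribozyme scaffold move relative to one another, and how those motions relate
to catalysis. The reference system is domain 1 (D1) of the *Oceanobacillus
iheyensis* group II intron — a ~270-nucleotide scaffold whose subdomains
(core D1c, peripheral D1c, D1d1, i1-i2) act as a gate controlling access of
the 3'-terminal domains to the active-site pocket — but every operation takes
arbitrary residue-range definitions and works on any RNA model.

## Scaffold descriptors

**Helical axes.** The axis of a subdomain is the total-least-squares 3D line
through its sugar-phosphate backbone atoms: the largest-variance principal
axis of the centred atom cloud, with the RMS perpendicular distance reported
as the fit residual. The default backbone atom set is
{P, OP1, OP2, O5', C5', C4', C3', O3'}; the sugar-ring atoms {C1', C2', O4'}
can be added through the registry. "Sugar-phosphate backbone" admits several
atom subsets; this default is frozen as the package convention and recorded
in every registry file, so any recalibration against reference structures is
a one-line configuration change rather than a code change.

**Axis orientation.** Principal axes are sign-ambiguous, so inter-axis angles
are only reproducible with an orientation rule. The directed convention
points each axis 5'→3' along the subdomain's first (lowest-numbered) strand
segment: from the centroid of that segment's first three residues toward its
last three. For single-range (hairpin) subdomains the orienting segment is
the first half of the range, i.e. from the open end toward the loop —
otherwise the head and tail of a hairpin are spatially adjacent and the sign
degenerates. Directed angles lie in [0°, 180°]; the undirected fold into
[0°, 90°] is co-reported on every descriptor record because published angle
values do not always state their convention.

**Descriptors.** Four inter-axis angles — A (core D1c vs D1d1), B (core vs
peripheral D1c), C (core D1c vs i1-i2), D (D1d1 vs i1-i2) — plus the *gate
distance*, the C1'–C1' distance between G75 and U238 (a scalar aperture
proxy for the D1 pocket), and the mass-unweighted radius of gyration over
the D1 range. Residues missing from a subdomain (disordered in cryo-EM
models) are skipped with a per-subdomain tally; an axis fit proceeds if at
least 6 atoms remain. The packaged registry
(`src/ribogate/data/oiheyensis_d1.yaml`) carries the D1 ranges in intron
numbering: core D1c 66–75/112–121, peripheral D1c 80–102, D1d1 124–133/
230–242, i1-i2 6–23/250–267, hinge 1 and hinge 2, and the gate atoms. Two
hinge-1 variants are in circulation (71–73 with 115–116, and 71–73 with
114–116 from base-pair-locking mutagenesis); the registry records both
rather than silently choosing.

## Superposition and displacement mapping

Rigid superposition uses the closed-form Kabsch solution (SVD with a
determinant correction to force a proper rotation). Optional iterative
outlier rejection discards atom pairs whose post-fit residual exceeds the
residual mean plus `reject_sigma` standard deviations and re-fits, for up to
`reject_cycles` cycles (default 5 cycles at 2.0 σ, the convention of common
alignment programs). Both the rejected and the all-pairs RMSD are always
reported so the convention is auditable. Displacement profiles superpose two
models over all shared heavy atoms (matched by chain, author residue number,
and atom name — no sequence-alignment fallback) and report the per-residue
distance between analogous atoms (default P), which localises conformational
change to specific nucleotides.

## Per-nucleotide conformation

η/θ pseudo-torsions use the standard (C4', P) convention:
η(i) = C4'(i−1)–P(i)–C4'(i)–P(i+1) and θ(i) = P(i)–C4'(i)–P(i+1)–C4'(i+1),
with the IUPAC sign convention, values in (−180°, 180°]. Chain termini,
numbering gaps (treated as strand breaks), and residues missing P or C4'
yield undefined flags, not exceptions.

Base flip classification measures the perpendicular distance of a
nucleobase-ring centroid (purine 9-ring or pyrimidine 6-ring atoms only; no
sugar contamination) from its helix axis, z-scored against the other
residues of the same helix. Labels use a hysteresis band — bulged out above
+2 σ, bulged in below +1 σ, indeterminate between — so borderline residues
are not forced into a state. The reference spread is floored at 10⁻⁶ Å so
that perfectly regular synthetic helices (zero spread) still classify a
genuinely displaced base correctly.

## Path-progress coordinates

Progress along a conformational transition is measured against an ordered
set of N milestone conformations X₁…X_N with

    spath = Σᵢ i·exp(−λ R(X−Xᵢ)) / Σᵢ exp(−λ R(X−Xᵢ)),    i = 1…N
    zpath = −(1/λ) · ln Σᵢ exp(−λ R(X−Xᵢ))

where R is the deviation of X from milestone i after optimal rigid
superposition — by default the mean-squared deviation in Å² (the PATHMSD
convention), so λ has units Å⁻²; RMSD is available as an alternative metric.
spath runs from 1 (first milestone) to N (last); zpath measures distance off
the path, bounded below by −ln(N)/λ. λ is rarely published, so the package
calibrates it with the standard heuristic λ = 2.3 / (mean adjacent-milestone
distance), which places neighbouring milestones ≈2.3 e-folds apart; the
value and whether it was calibrated are stored in the path's provenance.
Sums are evaluated with a max-shifted exponent (log-sum-exp); the naive form
exists only for cross-checks and underflows at large λR.

Milestone paths are built from an ordered ensemble by ranking frames on
their RMSD to the final (most open) frame and picking n frames evenly spaced
along that coordinate, each superposed onto the first. The default atom set
for milestones is the P atoms of the i1-i2 and core D1c ranges — the moving
portion of the scaffold; the exact subset used in any prior work is not
fixed by convention, so this choice is explicit and configurable.

## Ensemble quantification

For an ordered ensemble (e.g. 20 sub-state models from a 3D-variability
series) the package computes: a pairwise Kabsch RMSD matrix (no rejection)
over atoms common to *all* frames; a per-frame descriptor series
(best-effort per frame, since peripheral nucleotides may be structured in
only some sub-states); per-residue "tip" displacements of a subdomain
between two designated frames after superposition on the core subdomain; and
trend statistics (fraction of non-decreasing steps, range, endpoints).

## Splicing kinetics

Self-splicing is modelled as two sequential first-order steps,
precursor →(k₁) intermediate →(k₂) linear intron, with closed-form
populations (P + I + L = p₀ conserved; the k₁ = k₂ degenerate case uses the
continuous limit I = p₀k₁t·e^(−k₁t)). Rates are in min⁻¹; observations are
fractions of total lane signal. Fitting is nonlinear least squares over all
observed species simultaneously (lmfit Levenberg–Marquardt), multi-started
over a log-spaced rate grid because the product-only likelihood is symmetric
under k₁ ↔ k₂ exchange; product-only fits are flagged exchange-ambiguous and
report k₁ as the first step by convention. Standard errors come from the fit
covariance.

The spliced-exon-reopening (SER) assay is analysed by ordinary-least-squares
initial slopes (default: first 10 samples, after blank subtraction) followed
by a direct nonlinear Michaelis–Menten fit, v = v_max·S/(K_M + S). The
Lineweaver–Burk reciprocal-space line is reported for comparison only — the
double-reciprocal transform distorts the error structure and is never the
primary estimate. Mutant-vs-wild-type activity is reported as percentages at
full precision alongside the nearest-integer percent used in prose.

## Synthetic generators

The generators produce every input class the pipeline consumes:

* **Idealised duplexes** with canonical fibre-diffraction A-form parameters
  (32.7°/bp twist, 2.81 Å/bp rise) as defaults. Atoms sit on concentric
  helical tracks; the paired strand is placed by a C2 rotation about the
  axis, which cancels the axial cross-covariances so the least-squares axis
  equals the construction axis exactly, making angle recovery tests sharp.
  Bases are named pseudo-atoms on a ring template at a fixed radial offset —
  enough for flip classification, deliberately short of real nucleotide
  chemistry.
* **Four-helix scaffold mimics** with all pairwise inter-axis angles set by
  construction (an angle combination with no 3D realisation raises a
  geometry error) and the gate distance set by a pure translation, which
  leaves all angles unchanged.
* **Morphs and sweeps**: linear Cartesian morphs between two conformations,
  and per-descriptor sweeps in which a single helix rotates about its hinge
  point, emulating an ordered sub-state series.
* **Kinetic data**: two-step time courses (fractions clipped to [0, 1]) and
  Michaelis–Menten rate tables, with seeded Gaussian noise.

All generators are deterministic under a fixed seed. Default study
conditions used by tests and the acceptance script: coordinate noise
σ = 0.25–0.5 Å, 20-frame sweeps spanning the reported sub-state ranges
(angle A 65.8°→80.5°, gate 33.8→37.8 Å), 13 time points over 180 min at
k₁ = 0.016 / k₂ = 0.041 min⁻¹, and substrate concentrations 4–64 nmol·L⁻¹
at v_max = 22.47 nmol·L⁻¹·min⁻¹, K_M = 192.67 nmol·L⁻¹.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: sequence-dependent helix irregularity, non-duplex
motifs (bulges, junctions, tertiary contacts), partial disorder with
residue-wise missingness patterns of real cryo-EM models, correlated
experimental noise, and gel-quantification artefacts. Recovery tolerances on
synthetic constructs (±1° noiseless, ±2° at σ = 0.5 Å) therefore bound the
method's numerical error, not its accuracy on deposited models.

## Numerical choices

* Kabsch uses SVD with a det-sign correction; fits with fewer than 3 pairs
  (initially or after rejection) raise a degenerate-fit error.
* Axis fits flag, rather than fail, clouds whose two largest variances agree
  within 10⁻⁶ (ambiguous axis).
* Dihedrals raise on collinear triples (relative cross-product norm
  < 10⁻¹⁰).
* Path sums are log-sum-exp stabilised; spath is clamped only by
  construction (weights are a convex combination), never post hoc.
* The two-step fit switches to the k₁ = k₂ limit when |k₂−k₁| ≤ 10⁻¹² max(k).
* The simulation study for rate recovery uses 100 replicates and checks
  per-parameter 2-standard-error coverage (nominal ≈95%) against a 90%
  floor; a joint two-parameter criterion would sit exactly at its own
  nominal boundary and fail by chance in a large fraction of seed blocks.

## Reproduction of published reference values

The acceptance tests that reproduce printed descriptor and RMSD values of
deposited models (4Y1O, 4FAQ, 9G4I, 9G4V, 9G4L, 9G4J) read those entries
from `data/external/` at the repository root; the files are not shipped and
the tests fail with a download hint when they are absent. Because the exact
backbone atom subset and angle convention behind the published numbers are
not stated, the packaged defaults above are the package's own frozen
convention; users reproducing printed values should treat any residual
offset beyond the stated tolerances as a convention difference first and a
geometry difference second.

## Out of scope

Cryo-EM reconstruction and 3D-variability analysis themselves, MD engine
work and free-energy surface estimation (the path coordinates here are
analysis functions only, not biasing variables), SAXS data reduction and
profile fitting (including fit-quality χ² values), model refinement and
validation, and map-space computation are all out of scope: the package
consumes refined coordinate models and measures their geometry and kinetics.
Published free-energy levels, SAXS χ² values, map resolutions, and particle
counts are therefore not reproduction targets of this package.
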