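# Methods

This note documents the models, numerical conventions and design
choices behind each bclkit module, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Coordinate I/O

PDB files are parsed with gemmi and flattened to explicit atom records.
Conventions:

- **Altlocs** are collapsed to a single conformer per atom site: highest
  occupancy wins, ties go to the alphabetically first altloc identifier.
  The rule is deterministic and independent of record order.
- **Model selection** defaults to model 1; crystal structures carry one
  model, NMR ensembles must be addressed explicitly.
- **Elements** missing from columns 77–78 are inferred from the atom
  name (first non-digit character, with a short list of two-letter
  metal/halogen symbols trusted only when the name occupies the element
  column).
- **Residue numbering** is preserved exactly as deposited. BH3 work
  routinely mixes construct numbering with Uniprot numbering; mapping
  between schemes is left to the caller via an offset rather than
  guessed.
- Waters and heteroatoms are retained and flagged, never silently
  dropped; they are excluded from SASA and interface calculations by
  default.
- Coordinates are Ångström throughout; occupancies are clamped to
  [0, 1] on input.

When a deposited receptor:peptide complex does not document which chain
is which, `partition_chains_by_size` resolves it by Cα count (peptides
≤ 40 residues), since BH3 peptides (26–34-mers) are an order of
magnitude shorter than the receptor domain.

## Superposition and RMSD

`kabsch` computes the optimal proper rotation by SVD of the centred
cross-covariance: H = PᵀQ = U S Vᵀ, R = V·diag(1, 1, det(VUᵀ))·Uᵀ.
The determinant factor flips the smallest-singular-value axis whenever
the unconstrained optimum would be a reflection, so det(R) = +1 always.
RMSD is recomputed from transformed coordinates rather than from the
singular values, which keeps it exact in the reflection-corrected case.
Inputs of fewer than 3 pairs are rejected as under-determined.

The test suite checks `kabsch` against an independent quaternion
eigenvalue implementation (largest eigenvalue of the 4×4 key matrix) at
1e−9 Å on 1000 random instances, plus exact rigid-motion invariance and
symmetry.

`iterative_structure_align` handles chains with no prior residue
correspondence: pairs are seeded from a global sequence alignment
(BLOSUM62, gap open −11 / extend −1), or from the best gapless
sliding-window offset when the sequences are too dissimilar to seed at
least 3 pairs. It then alternates superposition with re-pairing of
mutually nearest Cα atoms within a cutoff (default 4.5 Å, a common
structure-alignment contact distance) until the pair set repeats, with
`max_iter` = 50 as an oscillation guard. Tie-breaks in the mutual
nearest-neighbour pairing follow the smallest residue-index pair.
The final pair count is a property of this algorithm and its cutoff;
it is not comparable to the aligned-atom counts reported by other
structure-alignment programs, so analyses should compare RMSD values,
not pair counts, across tools.

## Structure-based phylogeny

The distance between two structures is the Kabsch RMSD over "equivalent
Cα atoms": alignment columns of a user-supplied (typically
structure-guided) MSA where both rows are non-gap **and** both
structures resolve the residue's Cα. Each pair of structures is
superposed independently — no common reference frame — matching the
pairwise definition of the analysis. Pairs sharing fewer than 3 columns
raise an explicit overlap error (the default policy is to fail rather
than impute a missing matrix entry).

Clustering is agglomerative via scipy with **average linkage (UPGMA)**
by default; single/complete/ward are accepted. Average linkage was
chosen because it reproduces ultrametric input exactly and is the
customary choice for distance-matrix dendrograms of structural
similarity; the choice is exposed, not hard-coded. Newick export uses
the ultrametric convention that a leaf sits at half its cluster's merge
height, so a matrix with d(A,B) = 2, d(·,C) = 6 yields
`(C:3,(A:1,B:1):2);`.

The pipeline does not compute structure-guided alignments itself; it
consumes them. It also does not choose representative structures for
proteins with multiple depositions — the caller supplies the list.

## SASA and interfaces

SASA is Shrake–Rupley quadrature: each atom's sphere is expanded by the
probe radius (default 1.4 Å, a water-sized probe) and covered with a
golden-section spiral of 960 points (doubling the count changes totals
by <0.3 %; single isolated spheres agree with 4π(r+p)² to <0.5 %, and
two overlapping spheres with the closed-form cap expression to <0.5 %).
Per-atom area is the accessible point fraction × expanded-sphere area.

Radii are a NACCESS-style table: aliphatic C 1.87 Å; carbonyl,
carboxylate/amide/guanidinium and aromatic-ring C 1.76 Å; N 1.65 Å;
O 1.40 Å; S 1.85 Å; 1.80 Å default for anything else. An element with
no radius and no default raises, naming the atom.

**Orientation convention.** The quadrature directions are expressed in
a frame built from reference atoms of the molecule itself (first atom,
last atom, and the atom farthest from the line through them), so a
rigid motion of the input rotates the point set identically and SASA is
rigid-motion invariant to floating-point exactness. Principal-axis
frames were rejected because elongated symmetric molecules — helices —
have degenerate transverse moments, making eigenvectors unstable.
Interface calculations evaluate SASA(A), SASA(B) and SASA(A∪B) under
the **complex's** frame, so atoms far from the interface contribute
exactly zero ΔSASA rather than quadrature jitter.

Buried area is reported under both conventions in use in the
literature: the total ΔSASA = SASA(A) + SASA(B) − SASA(A∪B) (isolated
parts kept at complex coordinates) and the per-side "interface area"
ΔSASA/2, because published buried-surface figures do not always state
which convention they use.

Hydrogen bonds use heavy-atom geometry (crystal structures at typical
resolution carry no hydrogens): donor–acceptor distance ≤ 3.5 Å and
antecedent–donor–acceptor angle ≥ 90°, the standard permissive
geometric criteria. If a donor's covalent antecedent is missing the
angle test is waived rather than the bond discarded. Salt bridges pair
Arg NH1/NH2/NE, Lys NZ or His ND1/NE2 with Asp OD1/OD2 or Glu OE1/OE2
at ≤ 4.0 Å. All cutoffs are parameters.

Hot-spot burial quantifies how the groove engages the four conserved
BH3 hydrophobics: burial = 1 − SASA(side chain, complex) / SASA(side
chain, free peptide at complex coordinates), clamped to [0, 1].
"Engaged" is burial ≥ 0.7 by default, exposed as data rather than
asserted as a hard classification, since the interesting biology is
often precisely a hot spot that fails to reach the threshold. Glycine
hot spots report zero areas with a warning.

## BH3 motif scanning

The motif template fixes the spacing h1, h2 = h1+4, h3 = h1+7,
acid = h1+9, h4 = h1+11 (the spacing of the canonical V/L/F/D/V pattern
at peptide positions 71/75/78/80/82). Scoring: +2 for any of
{A,I,L,M,F,V,W,Y} at h1/h3/h4; +3 for Leu at h2, +1 for another
hydrophobic; +3 for Asp, +2 for Glu at the acid slot; default
`min_score` 10. The weights are deliberately simple — chosen so that
canonical BH3 sequences pass and poly-Ala fails — and are configurable;
the motif is short and weakly conserved, so no proteome-scale
sensitivity is claimed, and divergent motifs (the plausible case of
unrecognised BH3-only proteins in early-branching animals) may score
below threshold. Overlapping placements are resolved greedily,
best-score first. Coordinates are 1-based inclusive.

`peptide_window` cuts synthesis-ready windows with h1 at window
position 10, matching the offset of the first hot spot inside the
canonical 28-mer BH3 peptide construct; 26-mers (the common human
peptide length) use the same rule.

## ITC

The single-site model and the perfusion-cell dilution convention are
given in the `itc` module docstring: total concentrations follow the
MicroCal polynomial forms in the cumulative injected volume, bound
ligand solves the mass-action quadratic, and per-injection heats carry
the displaced-volume correction dQᵢ = Q(i) − Q(i−1) +
(dVᵢ/V₀)(Q(i)+Q(i−1))/2 + baseline. The cell working volume defaults
to 204.4 μl (iTC200-class instruments) and is configurable; protocol
defaults are 19 × 2.0 μl injections of 200 μM ligand into 20 μM
macromolecule at 25 °C. Units: M, μl, cal/mol, μcal; K_d is reported in
nM.

Fitting is trust-region least squares over (N, log₁₀K_a, ΔH, baseline)
with bounds (N ∈ [0.05, 10], log₁₀K_a ∈ [2, 12]), auto-initialised from
curve geometry (baseline from the final injections, ΔH from the net
heat, N from the molar ratio at the half-heat point) and restarted from
a log-K_a grid plus jittered starts (fixed RNG seed parameter); the
lowest-cost converged solution wins. Standard errors come from the
Gauss–Newton covariance; the log-K_a error propagates to a relative
K_d error. A flat thermogram — peak excursion below 5× the
injection-to-injection noise (MAD-based) — returns a **no-binding
verdict** with `converged = False` instead of a meaningless number.
An optional first-injection discard flag reflects common practice.
The Wiseman c = N·[M]₀·K_a is reported with every fit; in the c < 1
regime the K_d standard error grows by an order of magnitude, which is
the quantitative form of the usual "low-c fits are unreliable" caveat.

Simulation noise defaults: Gaussian with σ = 2 % of the largest
noise-free injection heat, the typical relative scatter of a
well-behaved instrument; the replicate simulations in the acceptance
script use 100 seeds per affinity regime, which bounds the Monte-Carlo
error of the mean recovered K_d to ~0.5 %.

## Crystal arithmetic

Cell volume uses the general triclinic closed form; the monoclinic case
reduces to a·b·c·sin β. Matthews coefficient V_m = V/(z·MW) with
solvent fraction 100·(1 − 1.23/V_m); 1.23 Da/Å³ is the standard
protein-density constant. V_m ≤ 1.23 is rejected as physically
implausible. Chain masses use Biopython's average residue masses (one
condensation water per chain); chains given as residue counts use a
110 Da mean residue mass. Construct masses from sequence databases
ignore expression-tag scars, so solvent-content comparisons against
published values carry a ±1–2 percentage-point uncertainty from the MW
alone.

Unique reflections are counted by enumerating all integer (h, k, l)
with d_max ≥ d(hkl) ≥ d_min via the reciprocal metric tensor, applying
the lattice-centering extinction (P/I/C/A/B/F), merging each orbit
under the Laue rotations plus Friedel inversion to its lexicographic
extreme, excluding (0,0,0), and scaling by completeness. Monoclinic
(Laue 2/m, unique axis b) and triclinic cells are supported; other
symmetries raise NotImplementedError rather than returning a wrong
count. The orbit-representative rule (lexicographic min vs max) is
asserted not to affect the count, and the P1 path is tested against a
brute-force loop enumeration. Counts follow the expected d_min⁻³
scaling to within 5 % over 3–1.85 Å.

## Synthetic fixtures

The generators produce geometry, not energetics:

- **Helices** are parametric Cα traces (rise 1.5 Å, twist 100°/residue,
  wheel radius 2.3 Å — ideal α-helix values giving the familiar 3.8 Å
  Cα–Cα spacing), optionally with outward CB pseudo-atoms; **bundles**
  place antiparallel helices on a circle. They exercise superposition,
  RMSD matrices and SASA but have no real side-chain packing, loops or
  sequence diversity, so passing tests demonstrate algorithmic
  correctness, not robustness to real crystallographic pathology
  (alternate conformers, chain breaks, disorder).
- **Noise** is iid per-axis Gaussian, seed-reproducible; clean-vs-noised
  RMSD converges to σ√3 (two independently noised copies: σ√6), which
  the tests verify over ≥100 seeds. Real coordinate error is neither
  isotropic nor iid.
- **Groove complexes** plant hydrogen bonds, salt bridges and fully
  caged hot-spot side chains at exact target distances, with a clash
  guard at 1.5 Å, and return a ground-truth sidecar so tests assert
  against the plan rather than the generator's internals. The "groove"
  is a set of placed contact atoms, not a real helical groove.
- **Motif sequences** embed the consensus template in flanks drawn from
  a zero-scoring alphabet, so detection tests are exact.

## Acceptance surface

`scripts/acceptance.py` recomputes the two headline numbers — mean
recovered K_d over 100 noisy replicate titrations at the 65 nM and
3760 nM regimes under the standard protocol — entirely from package
code at run time. Checks that require deposited coordinate sets or
sequence-database downloads (interface area of a specific crystal
structure, cross-family alignment RMSD, solvent content from
database-derived masses) are exercised on synthetic constructions and
closed-form oracles instead; the CLI runs the identical code paths on
any user-supplied files.

## Known limitations

- The iterative aligner is rigid; domain motions or flexible loops
  inflate its RMSD relative to flexible or fragment-based aligners.
- SASA ignores hydrogens and uses a single radii table; absolute areas
  shift by a few percent under alternative tables, which is one reason
  buried-area comparisons across programs need ~10 % tolerance.
- The ITC model is strictly 1:1 single-site; competitive, sequential or
  multi-site binding is out of scope, as is raw power-trace peak
  integration (heats are consumed pre-integrated).
- Reflection counting handles centering extinctions only — no screw-axis
  systematic absences (irrelevant for counts merged under the Laue
  group, where screw-axis absences fall on a measure-zero set of axial
  reflections) and no intensity statistics.
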