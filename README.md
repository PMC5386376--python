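# bclkit

Structural and biophysical analysis of Bcl-2 family receptor:BH3-peptide
systems — the kind of quantitative characterisation done when a new
pro-survival Bcl-2 homolog (for example, a sponge ortholog bound to a
Bak-like BH3 peptide) is solved and benchmarked against the known family.

It is aimed at structural biologists and biochemists who want scriptable,
testable versions of the steps usually spread across half a dozen GUI
programs:

- **Rigid-body superposition and Cα RMSD** (Kabsch SVD), including a
  sequence-seeded iterative aligner for chains without a prior residue
  correspondence.
- **Structure-based phylogeny**: pairwise Cα RMSD over the shared columns
  of a structure-guided alignment → distance matrix → agglomerative
  clustering → newick.
- **Interface characterisation**: Shrake–Rupley solvent-accessible surface
  area, buried interface area (ΔSASA = SASA(A) + SASA(B) − SASA(AB), with
  the per-side ΔSASA/2 convention also reported), hydrogen bonds and salt
  bridges on heavy-atom geometry, and fractional side-chain burial of the
  four BH3 hot-spot residues (h1–h4).
- **BH3 motif scanning**: a spacing template h1, h1+4 (conserved Leu),
  h1+7, h1+9 (conserved Asp/Glu), h1+11 with configurable position weights.
- **ITC**: simulation and nonlinear least-squares fitting of single-site
  isothermal titration calorimetry, reporting N, K_a, ΔH and
  K_d = 1/K_a, with a no-binding verdict for flat thermograms.
- **Crystal-content arithmetic**: triclinic cell volume, Matthews
  coefficient V_m = V/(z·MW) and solvent fraction 100·(1 − 1.23/V_m), and
  symmetry-unique reflection counts by direct Miller-index enumeration.
- **Synthetic data**: parametric helices/bundles, seeded Gaussian
  coordinate noise, peptide-in-groove toy complexes with exactly planted
  contacts, and motif-bearing sequences — every analysis stage can be
  tested offline against constructions with known ground truth.

## Worked example

Simulate a titration of a BH3 peptide binding at K_d = 65 nM under a
typical iTC200 protocol (19 × 2.0 μl of 200 μM ligand into 204.4 μl of
20 μM receptor; c = N·[M]/K_d ≈ 308) and fit it back:

```sh
$ bclkit itc simulate --kd-nm 65 --dh -10 --noise 0.02 --seed 1 --out itc.csv
$ bclkit itc fit itc.csv
Kd = 64.4 nM  N = 1.00  dH = -9.92 kcal/mol  (c = 310)
```

The fitted values recover the simulation truth (N = 1, ΔH = −10 kcal/mol,
K_d = 65 nM) to within the injected 2% heat noise; the reported c-value
confirms the sharply sigmoidal regime where such fits are reliable.

Crystal arithmetic for a monoclinic I-centred cell at 1.85 Å:

```sh
$ bclkit xtal stats --cell 68.31,51.59,107.80,90,96.34,90 --sg I2 --z 4 \
      --dmin 1.85 --dmax 41.08 --completeness 0.997
cell volume: 377575.9 Å³
unique reflections (41.08–1.85 Å): 31971
```

The count enumerates every Miller index in the resolution shell, applies
the body-centering extinction (h+k+l odd absent), merges each 2/m Laue
orbit (with Friedel mates) to one representative, and scales by the
completeness.

Scan a sequence for BH3 motifs and build a toy complex:

```sh
$ bclkit fixtures make --kind bh3 --seed 1 --out fx && bclkit bh3 scan fx/bh3.fasta
id	start	end	score	h1	h2	h3	h4	acid
synthetic_bh3	71	82	12	71	75	78	82	80
$ bclkit fixtures make --kind complex --out fx
$ bclkit interface report fx/groove_complex.pdb --receptor R --ligand P --hotspot 12
buried surface (ΔSASA): 555.3 Å² (per-side: 277.7 Å²)
hbonds: 2  salt bridges: 1
hotspot ('P', 12, ''): burial 1.00 (engaged)
```

## Layout

```
src/bclkit/      library modules (structure_io, superpose, structphylo,
                 sasa_interface, bh3_motif, itc, crystal_stats,
                 synthetic_data, pipeline, cli)
tests/           pytest suite incl. numeric acceptance checks
docs/methods.md  models, conventions, parameter choices, limitations
```
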