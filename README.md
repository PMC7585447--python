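# mcfold

All-atom **torsion-space Metropolis Monte Carlo** sampling of peptide folding
landscapes with a **generalized-Born + SASA implicit solvent**, plus the
analysis suite that turns trajectories into folding thermodynamics: fraction
of native contacts *Q*, potential of mean force *F(Q)*, barriers, folding
temperatures, contact maps, per-residue stability, φ-values, heat capacity,
RMSD, and hydrogen-bond distances.

## Who this is for

Molecular dynamics resolves bond vibrations and is therefore pinned to
femtosecond timesteps; a single folding event of even a miniprotein costs
enormous wall time. Monte Carlo in torsion space sidesteps the constraint:
every move is a rigid rotation of part of the molecule about a bond axis, so
no bond ever stretches, and a single accepted move can cross conformational
distance that would take thousands of MD steps. Combined with an implicit
solvent (no explicit water to move), this makes folding thermodynamics of
small proteins tractable on a desktop. mcfold is for researchers who want
that machinery with exact, testable energetics and fully reproducible runs.

## The model

The potential is an AMBER-style intramolecular force field plus implicit
solvation, all in kcal/mol, Å, radians:

```
E = Σ k_b (r − r0)²  +  Σ k_θ (θ − θ0)²  +  Σ k (1 + cos(nφ − φ0))
  + Σ_pairs [ 4ε ((σ/r')¹² − (σ/r')⁶) + k_e q_i q_j / (ε_p r') ]
  + ΔG_GB + γ · SASA + E_restraint
```

* **δ-regularization:** every interatomic distance entering Coulomb, LJ and
  GB terms is replaced by r' = r + δ with δ = 0.001 Å, keeping all terms
  finite even when a bold move proposes clashing atoms.
* **Generalized Born** (polar solvation): Still's pairwise form
  ΔG_GB = −(k_e/2)(1/ε_p − 1/ε_w) Σ q_i q_j / f_GB(r', B_i, B_j) with
  effective Born radii from HCT pairwise descreening and the OBC-II tanh
  rescaling. ε_p = 1, ε_w = 80 by default.
* **SASA** (nonpolar solvation): Shrake–Rupley quadrature with 960 sphere
  points per atom and probe 1.4 Å; E = γ·SASA with γ = 5.42 cal/mol/Å².
* **No cutoffs:** every pair sum is exact.

The move set consists of Gaussian single-dihedral pivots (width 20° by
default), endpoint-constrained concerted "crankshaft" moves over 4-residue
windows, and small whole-molecule rotations (≤ 5°) — all with symmetric
proposal densities, so plain Metropolis acceptance
min(1, exp(−ΔE/k_BT)) samples the Boltzmann distribution.

The reaction coordinate is the fraction of native contacts
**Q ∈ [0, 1]**: residue pairs (|i−j| ≥ 3) within 4.5 Å minimum heavy-atom
distance in a reference structure count as native; a contact is formed when
its current distance is below 1.2× its native value. Free-energy profiles
are F(Q) = −k_B T ln P(Q); the folding temperature is where folded and
unfolded minima are equally deep; an optional harmonic wall in Q keeps runs
out of regions they cannot escape on a finite budget.

## Worked example

```bash
mcfold fixtures --n-residues 6 --seed 1 --out .
mcfold prepare fixture_6res.pdb fixture_6res.top -o system.json
cat > run.yaml <<EOF
temperature: 400.0
n_steps: 2000
seed: 7
record_stride: 100
n_sphere_points: 242
reference_pdb: "fixture_6res.pdb"
EOF
mcfold run system.json run.yaml -o out
```

prints (abridged):

```
atoms: 62  residues: 6  rotatable dihedrals: 16
checksum: 4193bb1468b47f3c84f5985cae03c22c6b910faa43fcf6e7539804663b464a8f
seed: 7  T: 400.0 K  steps: 2000
T=400 K  accepted 784/2000 (ratio 0.392)
wrote manifest out/manifest.json
```

`fixtures` emits a synthetic 6-residue α-helical peptide with hydrogens and
a self-contained topology; `prepare` pairs structure with topology into a
checksummed bundle (16 rotatable φ/ψ/χ torsions found); `run` performs 2000
Metropolis steps at 400 K, accepting 39% of proposals, and writes a records
table (`step`, per-term energies, `Q`, running acceptance) plus a manifest
with seed, input checksums and output inventory — enough to reproduce the
run bit-for-bit. `mcfold analyze out/records_T400.tsv` then produces PMF,
barrier, occupancy and heat-capacity tables.

The same machinery drives multi-temperature series
(`temperatures: [360, 380, ...]` in the config) whose records feed
`folding_temperature`, `heat_capacity` and the contact-map/φ-value analyses
from `mcfold.analysis`.

## Layout

```
src/mcfold/model_io.py   structures, GROMACS-subset topologies, dihedral tree,
                         synthetic systems
src/mcfold/energy.py     bonded terms, LJ/Coulomb, OBC-II GB, Shrake-Rupley SASA
src/mcfold/moves.py      dihedral / concerted / rigid proposals
src/mcfold/sampler.py    Metropolis driver, Q restraint, temperature series
src/mcfold/analysis.py   Q, PMF, barriers, ensembles, φ-values, Cv, RMSD, H-bonds
src/mcfold/cli.py        prepare / run / analyze / fixtures commands
docs/methods.md          model details, defaults, numerical choices, limitations
```
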