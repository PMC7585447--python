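# Methods

This note documents the model, its defaults, the numerical choices, and what
the synthetic test systems do and do not establish.

## Potential energy

The total energy is a sum of AMBER-style intramolecular terms and an
implicit-solvent pair:

| term | form | notes |
|---|---|---|
| bonds | k_b (r − r0)² | k_b in kcal/mol/Å² (no ½ factor) |
| angles | k_θ (θ − θ0)² | k_θ in kcal/mol/rad² |
| torsions/impropers | k (1 + cos(nφ − φ0)) | periodic, one term per line |
| LJ | 4ε[(σ/r')¹² − (σ/r')⁶] | Lorentz–Berthelot combining |
| Coulomb | k_e q_i q_j/(ε_p r') | k_e = 332.0636 kcal·Å/mol/e² |
| GB | −(k_e/2)(1/ε_p − 1/ε_w) Σ q_i q_j/f_GB | Still's f_GB, incl. self terms |
| nonpolar | γ · SASA | γ = 5.42 cal/mol/Å² |
| restraint | k_Q (Q0 − Q)² for Q < Q0 | optional one-sided wall |

**Distance regularization.** r' = r + δ with δ = 0.001 Å applies to every
interatomic distance in the Coulomb, LJ and GB sums (never to GB self
terms, which use the bare Born radius). Monte Carlo proposes occasional
near-overlapping geometries; the offset keeps every term finite there while
being negligible (≲0.03% at 3 Å) in physical configurations.

**Exclusions and 1-4 scaling.** 1-2 and 1-3 pairs are excluded from the LJ
and Coulomb sums; 1-4 pairs are scaled by 0.5 (LJ) and 1/1.2 (Coulomb), the
convention of the AMBER force-field family whose functional forms we adopt.
GB and SASA see all atoms — solvation is not an exclusion-aware term.

**No cutoffs.** All pair sums run over all pairs. Neighbor filtering inside
the SASA kernel is exact (a sphere can only be buried by spheres that can
reach it), not an approximation.

## Generalized Born radii (OBC-II)

Born radii come from Hawkins–Cramer–Truhlar pairwise descreening with the
Onufriev–Bashford–Case tanh rescaling:

* offset intrinsic radii ρ_i = R_i − 0.009 Å, with R_i Bondi radii by
  default (H 1.2, C 1.7, N 1.55, O 1.52, S 1.8 Å);
* descreening scaling factors by element: H 0.85, C 0.72, N 0.79, O 0.85,
  S 0.96, default 0.80;
* Ψ_i = ρ_i Σ_j H(r'_ij, ρ_i, S_j ρ_j), and
  B_i = [ρ_i⁻¹ − tanh(αΨ − βΨ² + γΨ³)/R_i]⁻¹ with α = 1.0, β = 0.8,
  γ = 4.85.

An isolated atom's Born radius is exactly its offset intrinsic radius;
burial can only increase it. All flavor parameters live in
`SolventModelParams`, so other GB variants can be configured without code
changes. The tests check the buried-atom radius against a Coulomb-field
volume-integration oracle on a grid; that comparison is run with unit
scaling factors on a non-overlapping cluster, because the sub-unity factors
exist precisely to compensate vdW-sphere overlap in real molecules and
would bias an overlap-free comparison.

## SASA

Shrake–Rupley with a deterministic Fibonacci (golden-spiral) point set,
960 points per atom by default (configurable; the isolated-sphere area is
exact at any count, and two-sphere closed forms are reproduced to <0.5% at
the default). Atomic radii are LJ minimum-distance radii r_i = 2^(1/6)σ_i/2
with a 1.4 Å water probe.

The quadrature directions are expressed in a molecule-fixed frame (principal
axes of the coordinate cloud, signs fixed by the first atom with a
non-negligible projection, third axis by cross product). A lab-fixed grid
would make the total energy jitter by ~10⁻⁴ kcal/mol under rigid rotations;
with the molecule-fixed frame the energy is rotation-invariant to floating
point (~10⁻¹³ kcal/mol), which the rigid-rotation move relies on. The frame
is ill-conditioned only for degenerate inertia tensors (perfectly linear or
spherically symmetric clouds), which do not occur for peptides.

## Move set

All proposals are rigid rotations of an atom subset about an axis whose
atoms do not move, so **no move ever changes a bond length** — this is what
removes the femtosecond timescale constraint.

* **Dihedral pivot** (default weight 0.45): one uniformly chosen rotatable
  torsion, Δθ ~ N(0, width²); width 20° by default (18.3–20° are the values
  appropriate for proteins in the 20–36-residue range). Rotatable torsions
  are φ/ψ/χ; amide ω bonds, ring bonds and proline φ are never rotatable.
  The downstream atom set of each torsion is the connected component on the
  far side of the axis — rotating it changes no distance among the
  remaining atoms.
* **Concerted crankshaft** (default weight 0.45): a uniformly chosen
  interior 4-residue window; the atoms strictly between the window-start N
  and window-end C (graph sense: the component left after deleting both
  anchors) rotate rigidly about the anchor–anchor axis by Δθ ~ N(0, width²).
  Endpoints are exactly fixed; only the two junction bond angles change, and
  the angle term scores them. This realizes the endpoint constraint without
  a loop-closure solver; an analytic loop-closure variant could be swapped
  in behind the same interface.
* **Rigid rotation** (default weight 0.10): whole molecule about a random
  axis through the geometric center, angle uniform on [0, 5°]. The share is
  a package choice: small, because the move only decorrelates the
  lab-frame orientation, while dihedral and concerted moves keep the
  stated equal probability relative to each other. No translation moves —
  with an implicit solvent there is no box and the energy is
  translation-invariant.

"Width" is interpreted as the standard deviation of the Gaussian. All
kernels are symmetric (q(x→x') = q(x'→x)), verified in tests by applying
the recorded inverse transform, so Metropolis acceptance needs no Hastings
correction.

## Sampler

`min(1, exp(−ΔE/k_B T))` acceptance with k_B = 1.9872041×10⁻³ kcal/mol/K.
Energies are **fully recomputed for every proposal**: the GB and SASA terms
are global, so incremental updates are unsafe without careful invalidation;
correctness is preferred over speed, and the jitted kernels make full
recomputation affordable at fixture scale. A rejected step leaves the state
bit-identical (proposals operate on copies).

Runs record every `record_stride` steps; the first 10% of records (default)
are flagged as equilibration and excluded from all ensemble statistics while
remaining in the raw output. A temperature series derives per-temperature
seeds as base seed + index. Everything stochastic flows through one named
`numpy` generator seeded from the config, making runs bit-reproducible; the
CLI writes the seed and input checksums into the run manifest.

The optional Q restraint is a one-sided harmonic wall k_Q(Q0 − Q)² below
Q0 (defaults Q0 = 0.4, k_Q = 100 kcal/mol per unit Q²), continuous with
continuous derivative at the wall. It exists for systems (β-sheets) whose
fully melted states do not refold on accessible budgets.

## Analysis conventions

* **Native contacts:** heavy-atom minimum distance < 4.5 Å between residues
  with |i−j| ≥ 3; formation tolerance λ = 1.2; the reference is any
  designated frame (typically a relaxed lowest-energy structure) and is
  recorded. All four knobs are configuration — reported Q values shift with
  the definition, so comparisons must hold it fixed. The hard count is the
  default because the Q restraint needs a concrete per-frame Q.
* **PMF:** 50 bins over [0, 1] by default, F = −k_B T ln P shifted to
  min 0; empty bins are masked (NaN), never zero-filled, so barrier
  detection sees no smoothing artifacts. Minima are bins strictly below
  both neighbors (endpoints compare to their one neighbor); each barrier is
  reported from both flanking minima (the ΔG_N,I / ΔG_I,N convention).
* **Folding temperature:** linear interpolation in T of
  ΔF = F(folded) − F(unfolded) to zero; "outside range" (None) when ΔF
  never changes sign. Temperature calibration is a uniform user-supplied
  shift applied to reported axes only; raw temperatures stay in outputs.
* **Ensembles:** labeled Q intervals, closed on the left, open on the right
  (upper bound 1.0 inclusive so the native frame is assignable). Default
  transition-state window Q ∈ [0.55, 0.65].
* **φ-values:** within each of N/TS/D, frames are Boltzmann-weighted by
  their recorded energies (weights shifted by the ensemble minimum for
  stability; identical energies give uniform weights);
  φ_i = (⟨q_i⟩_TS − ⟨q_i⟩_D)/(⟨q_i⟩_N − ⟨q_i⟩_D) by default, with the raw
  ⟨q_i⟩_TS always reported alongside. Residues with undefined q_i or
  denominator magnitude < 0.01 are flagged, not clipped: out-of-[0,1]
  values are information about ensemble overlap, not errors to hide.
* **Heat capacity:** Cv = var(E)/(k_B T²) on post-equilibration samples,
  population variance.
* **RMSD:** proper-rotation Kabsch superposition (scipy `align_vectors`),
  selections all-atom / backbone (N, CA, C, O) / Cα.

## Synthetic systems

`generate_fixture_peptide` builds an alanine-like chain (10 atoms per
residue + 2 terminal atoms) with ideal internal coordinates, α-helical
backbone torsions (φ = −60°, ψ = −45°) with seeded 6° jitter, per-residue
charges summing to zero, element-based LJ/Bondi parameters (polar hydrogens
get the small AMBER-style σ = 1.07 Å), and harmonic equilibria set to the
constructed geometry — so the generated structure is an exact minimum of
the bond and angle terms, which gives the energy tests clean zeros.

`make_single_dihedral_system` is a 4-atom chain whose only non-constant
term is one torsion V(φ) = k(1 + cos(nφ − φ0)): its Boltzmann density is
known in closed form, making it the canonical end-to-end sampler oracle.
The χ² comparison thins the chain (every 100th of 10⁶ steps, 36 bins)
because raw MC samples are autocorrelated and would overdisperse the
statistic; the thinning interval was chosen from the move width (30°) and
the potential scale before measuring, not tuned to outcomes.

What the fixtures do **not** emulate: real side-chain diversity and their
rotamer barriers, disulfides, prolines/glycines (covered only by targeted
topology-edit tests), NMR-model heterogeneity of real references, and the
slow collective kinetics of β-nucleation. Passing tests therefore establish
the correctness of the energies, moves, estimator formulas and bookkeeping —
not the biophysical accuracy of any particular force-field parameterization
on real proteins.

## Problem sizes and defaults used in validation

Validation runs use 4-atom toys (10⁶ steps), 22–102-atom synthetic peptides
(brute-force oracle comparisons), and 2000-step full-potential runs with 242
SASA points — sizes chosen so the whole suite and the acceptance script each
complete in minutes on one CPU while still exercising every code path at
full numerical strictness (oracle agreement to 10⁻⁹ kcal/mol where exact).
Production-scale runs (10⁸ steps, 300-atom proteins) use the same code
paths; only `n_steps`, `n_sphere_points` and recording strides differ.

## Known limitations

* The implicit solvent has no temperature dependence; folding temperatures
  from GB/SASA models are systematically high relative to experiment, and
  salt bridges are over-stabilized. The analysis module's uniform
  temperature-shift calibration exists for exactly this bias.
* Born radii use OBC-II pairwise descreening; power-diagram-based radii and
  surface areas are out of scope, as are Poisson–Boltzmann and 3D-RISM
  references.
* Energies are recomputed in full per step; an incremental scheme gated by
  a self-audit against full recomputation is a possible optimization, not
  implemented.
* No kinetics: Monte Carlo step counts are not physical time, and no rate
  reconstruction is attempted.
* Hydrogens must be present in inputs; no protonation or parameter
  assignment is performed (topologies arrive pre-assigned).
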