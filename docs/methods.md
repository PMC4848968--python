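# Methods

`mutddg` predicts the change in folding free energy (ΔΔG, kcal/mol) caused by
a single amino-acid substitution in a protein of known structure.  The
prediction is a weighted linear combination of MM/PBSA-style energy terms and
knowledge-based terms, with two separate weight sets chosen by a statistical
flag system.  This note records the model, its assumptions, the numerical
choices, and what the synthetic test data does and does not demonstrate.

## The thermodynamic model

Folding free energy change is approximated through four structures: the
folded wild type (WT), the folded mutant (MT), and two 3-residue segments
(the mutated residue plus one neighbor on each side) cut from each folded
structure to represent the unfolded state.  The locality assumption is that a
point substitution perturbs the unfolded ensemble only near the site, so all
distant unfolded-state contributions cancel between WT and MT:

    ΔΔG ≈ [G(MT) − G3(MT)] − [G(WT) − G3(WT)]

Each energy term E contributes through the double difference
ΔΔE = [E(MT) − E(WT)] − [E(MT_seg) − E(WT_seg)].  Segment length is fixed at
three residues; at a chain terminus the segment degrades to two residues with
a logged warning.  Segment termini are left uncapped: the bonded terms across
the cut bonds are simply absent, identically for WT and MT, so they cancel in
the differences.

## Features

| feature   | meaning                                          | units        |
|-----------|--------------------------------------------------|--------------|
| ΔIE       | internal (bond+angle+dihedral+improper) MT − WT  | kcal/mol     |
| ΔΔIE      | double difference of IE                          | kcal/mol     |
| ΔΔVE      | double difference of Lennard-Jones energy        | kcal/mol     |
| ΔΔEE      | double difference of group-dielectric Coulomb    | kcal/mol     |
| ΔΔSP      | double difference of PB reaction-field energy    | kcal/mol     |
| ΔS        | site side-chain entropy MT − WT                  | –            |
| ΔSsum     | total side-chain entropy MT − WT                 | –            |
| SAS_MT    | total mutant SASA                                | Å²           |
| SN/SAS_MT | nonpolar solvation per area of the mutant        | kcal/mol/Å²  |
| ΔHYDR     | hydropathy-scale difference MT − WT              | –            |

Side-chain entropy uses S = ln[rSASA·(R−1)+1], where R is the maximal rotamer
count of the residue type: a fully buried residue is assumed frozen into one
rotamer (S = 0) and a fully exposed one samples all R.  The bundled R values
are maximal χ-combination counts (Gly/Ala 1, Ser/Cys/Thr/Val 3, …, Lys/Arg 81);
they are provisional and replaceable through the API.

The nonpolar solvation term is SN = γ·SAS + β with γ = 0.005 kcal/mol/Å² and
β = 0.86 kcal/mol.  Because SN is affine in SAS, SN/SAS varies only through
the β/SAS part; the term is kept because the pooled model's published fit
retains it, and backwards elimination can drop it on refit.

ΔHYDR is the Kyte–Doolittle hydropathy difference.  It appears only in the
pooled (no-flag) model; the hydropathy scale behind the published weight was
not specified, so the bundled scale is a documented stand-in and the weight
should be refit for quantitative use of the pooled model.

## The flag system and the two regimes

A mutation is described by four categories: WT residue type, MT residue type,
the burial pair (WT burial, MT burial) and the SSE pair.  For each category
the bundled tables give the probability that a mutation in that category
changes stability by at least 1 kcal/mol ("large effect"), estimated as

    P = (Mlarge / M) · (1 + ΔN),      ΔN = Nlarge/Nsmall − 1

where ΔN corrects for the overall imbalance between large and small cases in
the source database (bundled value 0.069).  Categories with fewer than 5
cases get the uninformative value 0.5.  A single alteration pass rescales
each |ΔΔG| by the other three flags' probabilities —
(2/3)·ΣP_j·|ΔΔG| below the cutoff, (2/3)·Σ(1−P_j)·|ΔΔG| at or above — and the
probabilities re-estimated from the altered values (P′, with ΔN recomputed on
the altered values) are the ones used at prediction time.  The mean of the
four P′ values selects the regime: large iff P ≥ 0.5 (the boundary counts as
large).  Burial classes are B (rSASA ≤ 0.001), PE (≤ 0.25) and E (> 0.25);
the 0.001 threshold replaces an exact-zero test because numeric SASA rarely
returns exactly zero.

Small-regime model:  ΔΔG = w0 + w1·ΔIE + w2·ΔΔVE + w3·ΔΔSP + w4·ΔΔEE + w5·ΔSsum
Large-regime model:  ΔΔG = w0 + w2·ΔΔVE + w3·ΔΔSP + w4·ΔΔEE + w5·ΔS + w6·ΔSsum
                             + w7·SAS_MT + w8·SN/SAS_MT

The published small-regime weight table lists a single internal-energy weight
(for ΔIE) and none for ΔΔIE, although the small-regime formula names both.
The bundled set therefore carries the published five weights; ΔΔIE remains in
the small regime's term vocabulary so a refit can assign it a weight.  A
pooled "all" weight set (no flags) is also bundled.

## The energy model and its deliberate differences

The original protocol minimized all-atom structures with a
Generalized-Born molecular dynamics engine, repacked side chains with a
dedicated rotamer-refinement tool, and computed electrostatics with an
external FD-PB package.  This package is self-contained and replaces those
stages:

- **Heavy-atom force field.**  Hydrogens are never built; hydrogen charges
  are folded onto the parent heavy atom.  Residue net charges are exact
  formal charges (remainder correction onto CB, CA for Gly).  LJ parameters
  and radii are element-class values.  Bond/angle/improper equilibria are
  measured from a reference build of each residue's internal-coordinate
  template, so ideally built structures sit at ~zero bonded energy; force
  constants are module constants (bond 300 kcal/mol/Å², angle 60 and improper
  30 kcal/mol/rad²).  The only torsion carrying a barrier is the peptide ω
  (2-fold, 3 kcal/mol); side-chain torsional stiffness is represented by the
  discreteness of the rotamer set rather than by cosine terms.  1-2 and 1-3
  nonbonded pairs are excluded, 1-4 pairs are unscaled.
- **Side-chain placement.**  A bundled coarse rotamer set (staggered sp3 χ
  values, a few canonical placements for terminal sp2 χ) scored by a
  quadratic steric-overlap penalty against the rest of the structure; ties go
  to the lowest rotamer index.  The wild type is rebuilt through the same
  operator (X→X), so template error cancels in the differences, and a
  self-mutation yields an exactly zero feature vector.
- **Relaxation.**  Optional steepest descent with backtracking on
  bonded + LJ + solvent-screened Coulomb (ε = 80), replacing the original
  3000-step GB minimization.  Energy is non-increasing across accepted steps;
  the run stops at the step limit or when the gradient norm drops below
  0.1 kcal/mol/Å.  The prediction CLI defaults to 0 steps (template-exact
  geometry); the API default is 200.
- **Electrostatics.**  Residue-group dielectrics: 22 for charged (R,K,H,D,E),
  20 for polar (S,T,N,Q,Y), 20 for the rest, 80 for solvent.  The Coulomb
  term needs a pairwise rule, which a grid solver does not define; the
  geometric mean of the two atoms' class values is used (arithmetic mean
  available by configuration).  The polar solvation term SP is half the sum
  of q·Δφ over atoms, where Δφ is the difference between two FD solves on
  the same grid: solvated (solvent dielectric outside the solute) minus
  uniform (the solute's dielectric map continued everywhere, each node taking
  the nearest atom's class).  The grid self-energy cancels between the two
  solves because the charge distribution and the dielectric at the charges
  are identical.  Grid: cubic, scale 1 grid/Å by default, molecule filling
  70% of the edge, trilinear charge spreading (conserves total charge to
  1e-9 e), harmonic-mean face dielectrics, Dirichlet boundary from the
  analytic screened-monopole potential.  Zero ionic strength by default, so
  linear PB reduces to the Poisson equation; κ is a config knob.  The solver
  is red-black SOR (ω = 1.9), which is deterministic and vectorizes; it
  agrees with a direct sparse-LU solve of the identical system to 1e-8.
  On the Born-ion benchmark (q = 1e, R = 2 Å, ε 1/80) the two-solve scheme is
  within 6% of the closed form at scale 1 and 4% at scale 2.
- **SASA.**  Shrake–Rupley with a deterministic golden-spiral point set (960
  points per atom, no RNG), probe 1.4 Å.  rSASA normalizes by the
  central-residue SASA of an extended Gly-X-Gly tripeptide computed with the
  same algorithm and bundled as data, so the normalization is self-consistent
  rather than borrowed from an external convention.
- **Secondary structure.**  An internal assigner with the 5-class vocabulary
  H/C/T/S/B: backbone N···O H-bonds (distance < 3.5 Å, C=O···N angle ≥ 90°),
  runs of ≥ 4 consecutive i,i+4 bonds → H, mutual inter-strand H-bond rungs
  forming ladders → S (isolated rungs → B), i,i+3 bonds → T, else C.

Because the energy stack differs from the one the published weights were
fitted on, predictions with the bundled weights are approximations (reports
carry `weights_provenance` and an `energy_model` note), and the training
module exists to refit the weights against a labeled dataset computed with
this package's own features.

## Training machinery

Weights are fitted by ordinary least squares with an intercept; p-values are
classical two-sided t-tests.  Backwards elimination repeatedly removes the
highest-p term at or above α = 0.05 and refits; the intercept is never
removed and the elimination order is logged.  Cross-validation shuffles with
a seeded generator, splits into k contiguous folds (k = 5 by default) and
reports the mean held-out Pearson R; fold construction was not specified by
the source method, so the seeded-shuffle convention is this package's choice,
with the seed recorded.  When both regimes are refit, the regime split
follows the predicted flags, not the experimental |ΔΔG|, and the final R
pools both regimes' predictions into one correlation.  The dielectric-scan
harness refits an EE+VE+SP regression for every (ε_charged, ε_polar, ε_other)
triple of a user-supplied grid and records the R surface.

## Dataset curation

Experimental tables are cleaned in a fixed order: exact duplicates dropped;
entries outside pH 5–9 dropped; repeated measurements of the same mutation
fused to their mean when they span < 0.1 kcal/mol and dropped entirely
otherwise.  Every rule's removals are counted in an audit log.  The knowledge
layer works with |ΔΔG| only, so the sign convention of the source database
does not affect the flags.

## What the synthetic data shows — and what it does not

The fixtures module generates ideal-geometry peptides (helix −57/−47,
extended −120/+120, antiparallel sheet pairs placed by a deterministic
H-bond-maximizing search) and labeled datasets in which the four flags are
conditionally independent given the large/small class, so that each
category's large-effect rate converges to a specified value; |ΔΔG| magnitudes
are log-normal on each side of the 1 kcal/mol cutoff.  Defaults are balanced
(all rates 0.5, no class imbalance), the fixed point of the flag machinery.

Passing tests on these fixtures demonstrates internal correctness —
closed-form physics (Coulomb, LJ, Born, sphere SASA), exact statistical
identities, parameter recovery within binomial/standard error, and end-to-end
determinism.  They do not demonstrate predictive accuracy on real proteins:
ideal peptides have no packed cores, crystallographic noise, or missing
atoms, and the synthetic flag data has no correlation structure between
flags.  The published benchmark correlation on a curated experimental
database is not reproducible without that database and the original energy
stack, and is out of scope here.

## Numerical choices and degenerate inputs

- Problem sizes in the test-suite simulations (n = 500–6000 for statistical
  recovery, ≤ 15³ grids for the solver-equivalence check, 12-residue
  peptides for end-to-end runs) were chosen as the smallest sizes at which
  the assertions are statistically meaningful.
- SOR convergence: relative residual < 1e-6 (default), hard iteration cap
  20000 with a diagnostic error on non-convergence; zero-charge grids return
  an identically zero potential.
- Alternate locations: highest occupancy wins, ties go to altloc 'A'.
  Multi-model files: first model only (single-conformer method).
- Non-canonical residues are rejected with a clear error; residues missing
  backbone atoms are dropped with a warning at read time; a mutation site
  with a wrong expected wild type reports the residue actually present.
- Unknown flag categories fall back to probability 0.5 with a warning (the
  sparse-category rule generalized).
- MCC returns 0 with a warning when a confusion-matrix marginal is empty;
  Pearson R of a constant vector is reported as 0 with a warning.

## Known limitations

- The heavy-atom energy model is deliberately simple; its absolute energies
  are not comparable to all-atom force fields, and the bundled published
  weights are therefore approximate in this stack (refit for quantitative
  work).
- Rings carry no planarity impropers beyond their bond/angle network; long
  relaxations of aromatic residues may pucker slightly.
- The rotamer set is coarse (no backbone-dependent library); buried
  mutations into large residues may be placed with residual clashes.
- No pH dependence, no ligands/cofactors, no mmCIF input, single chain per
  prediction.
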