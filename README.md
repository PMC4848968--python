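# mutddg

Structure-based prediction of folding free energy changes (ΔΔG) for single
amino-acid substitutions, for protein scientists who want not just a number
but the energy decomposition and the built mutant structure behind it.

A point mutation stabilizes or destabilizes a protein by an amount
ΔΔG = ΔG_fold(MT) − ΔG_fold(WT).  `mutddg` estimates it from a PDB structure
with a knowledge-modified MM/PBSA model: molecular-mechanics terms (bonded
internal energy IE, Lennard-Jones VE), continuum electrostatics
(group-dielectric Coulomb EE and finite-difference Poisson–Boltzmann
reaction-field solvation SP), surface-area nonpolar solvation, and
knowledge-based terms (side-chain entropy S = ln[rSASA·(R−1)+1], hydropathy).
The unfolded state is modeled by 3-residue segments cut from the folded
structures, so each energy term enters as a double difference

    ΔΔE = [E(MT) − E(WT)] − [E(MT_seg) − E(WT_seg)]

and the prediction is an affine model over the features, e.g. for the
small-effect regime

    ΔΔG = w0 + w1·ΔIE + w2·ΔΔVE + w3·ΔΔSP + w4·ΔΔEE + w5·ΔSsum.

Which of two weight sets applies is decided by four statistical flags — the
probabilities that a mutation of this WT type, MT type, burial pair and
secondary-structure pair causes a change ≥ 1 kcal/mol, corrected for class
imbalance (P = Mlarge/M·(1+ΔN)).  Their mean ≥ 0.5 selects the large-effect
model.  The package also contains the full training machinery (OLS with
backwards elimination at p < 0.05, 5-fold cross-validation, dielectric-scan
harness) to refit the weights, and a fixtures module that generates
ideal-geometry peptides and synthetic labeled datasets so everything is
testable without downloads.  See `docs/methods.md` for the model details and
the deliberate differences from the original all-atom protocol.

## Worked example

Build a small ideal helix fixture and score a Gly→Trp substitution at
position 6 of chain A:

```python
from mutddg.synth import make_peptide
from mutddg.structure import write_pdb
write_pdb(make_peptide("AAVAAGAAVAAA", "helix"), "helix.pdb")
```

```sh
mutddg predict --pdb helix.pdb --chain A --pos 6 --wt G --mt W \
    --relax-steps 0 --out result.json
```

The JSON report contains (abridged, values as printed by the run above):

```
ddg_pred                -1.143        predicted ΔΔG, kcal/mol
regime                  small         combined flag probability 0.46 < 0.5
site_codes              loc E-E, sse HH   exposed helix site in WT and MT
features.dd_ve          -3.036        LJ double difference, kcal/mol
features.d_ssum          1.415        entropy gain (Trp is flexible, exposed)
contributions.dd_ve     -0.228        weight × feature, kcal/mol
contributions.intercept -0.744        small-regime intercept
```

Reading it: the site is solvent-exposed in a helix, its flag probabilities
(0.57, 0.45, 0.29, 0.53) average to 0.46, so the small-effect model applies;
the prediction is the intercept −0.744 plus the weighted feature
contributions, here dominated by the van der Waals double difference — a
mildly destabilizing −1.14 kcal/mol (negative values are destabilizing in
this convention).  The report also carries every flag, feature, weight
provenance and the config echo; `--write-structures` additionally saves the
built WT and MT models as PDB files.

Refit weights from a feature table and reuse them:

```sh
mutddg train --features my_features.tsv --out my_weights.tsv --seed 1
mutddg predict --pdb helix.pdb --chain A --pos 6 --wt G --mt W \
    --weights my_weights.tsv --out result.json
```

Build probability tables from a labeled mutation table (curation audit is
printed):

```sh
mutddg tables --data protherm_like.tsv --out my_tables.tsv
```

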