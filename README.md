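# dnahotspot

Hot-spot residues are the handful of interface residues that contribute a
disproportionate share of a protein–DNA complex's binding affinity: mutating
one changes the binding free energy by ΔΔG ≥ 1.0 kcal/mol. Finding them by
alanine scanning is slow and expensive, so structural biologists and protein
engineers want them predicted from the complex structure. `dnahotspot` is a
library + CLI that implements that pipeline end to end:

1. **Interface calling** from a PDB structure by two rules — solvent
   accessibility loss on binding (ΔASA > 1 Å² with unbound RASA > 5%) and
   heavy-atom distance to DNA (< 5 Å) — combined by union.
2. **Featurization** of interface residues: ten centralities of a
   distance-weighted residue interaction network (typed hydrogen-bond /
   van der Waals / disulfide / salt-bridge / π–π / π–cation contacts),
   solvent exposure (SASA, RASA, half-sphere exposure, contact number,
   residue depth), B-factor, hydrogen-bond counts, BLOSUM62 scores, eight
   physicochemical scales, conservation and local structural entropy —
   plus readers for externally predicted features (PSI-BLAST PSSM, DSSP,
   secondary-structure/RSA predictor tables).
3. **Dataset construction** from ΔΔG mutation tables: wild-type validation,
   interface filtering, hot/non-hot labeling at the 1.0 kcal/mol threshold,
   >40%-identity redundancy removal, leakage-free complex-level splits.
4. **Feature selection** by sequential backward selection (SBS) driven by
   the criterion

       E_c = mean_repeats( mean_folds( ACC + SEN + SPE + MCC + AUC ) )

   over repeated stratified 10-fold cross-validation: each round evaluates
   every leave-one-out subset under paired fold seeds and stops when no
   removal strictly improves E_c.
5. **Classification** with an ensemble stacking classifier (ESC): three
   gradient-boosting base learners (XGBoost, LightGBM, sklearn gradient
   tree boosting) feeding a logistic-regression meta-model trained on
   out-of-fold base probabilities; an ensemble vote classifier (EVC,
   mean of member probabilities) is included for comparison.

A synthetic-fixture generator (ideal α-helix beside an idealized DNA
duplex with a known-by-construction interface; planted-signal feature
tables) makes every stage testable without external data.

## Worked example

```python
from dnahotspot import (ToyComplexSpec, make_toy_complex, interface_calls,
                        assemble_features)

pdb_text, truth, cx = make_toy_complex(ToyComplexSpec(seed=1))
print(sorted(k[1] for k in truth))          # [1, 5, 8, 12]

for c in interface_calls(cx, "A"):
    if c.is_interface:
        print(f"res {c.key[1]:2d}  dASA={c.delta_asa:6.1f} A^2  "
              f"RASA={c.rasa_unbound:5.1f}%  min_dist={c.min_dist_to_dna:5.2f} A")
```

prints one line per interface residue:

```
res  1  dASA=  43.2 A^2  RASA= 51.7%  min_dist= 4.15 A
res  4  dASA=   8.4 A^2  RASA= 34.7%  min_dist= 5.43 A
res  5  dASA=  21.8 A^2  RASA= 58.7%  min_dist= 4.38 A
res  8  dASA=  39.5 A^2  RASA= 33.7%  min_dist= 3.82 A
res 12  dASA=  47.2 A^2  RASA= 64.7%  min_dist= 3.50 A
```

Residues 1, 5, 8 and 12 are the constructed contact face (distance rule,
matching the generator's ground truth exactly); residue 4 is picked up by
the accessibility rule alone — it sits 5.4 Å away but still loses 8.4 Å²
of accessible area on binding. Features for the contact set:

```python
table = assemble_features(cx, "A", sorted(truth))
print(table.df.shape)                       # (4, 48)
```

48 internally computed columns per residue (`rin_*` centralities, exposure,
BLOSUM row, physicochemical scales, ...), each tagged with its provenance.

The same flow from the shell:

```sh
dnahotspot fixtures --seed 3 --out-dir fx          # toy complex bundle
dnahotspot extract fx/toy_complex.pdb --out-dir ex # interface + features
dnahotspot build-dataset fx/mutations.tsv fx/toy_complex.pdb --out ds.tsv
# -> "wrote ds.tsv: 4 labeled samples (2 hot)"
dnahotspot train ex/…  /  dnahotspot select …  /  dnahotspot predict …
```

`train` writes a model archive and a CV report with the seven metrics
(ACC, SEN, SPE, PRE, F1, MCC, AUC); `select` writes the SBS trace
(round, removed feature, E_c) and the selected feature list; `predict`
writes per-residue hot-spot probabilities sorted by confidence.

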