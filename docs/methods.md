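# Methods

`dnahotspot` predicts hot-spot residues — interface residues whose mutation
changes the protein–DNA binding free energy by ΔΔG ≥ 1.0 kcal/mol — from
the structure of a protein–DNA complex. This note documents the models,
the numerical choices, what the synthetic fixtures emulate, and the known
limitations.

## Interface definition

A protein residue is an interface residue by the union (configurable to
intersection) of two rules:

* **Accessibility rule.** ΔASA > 1 Å² between the protein chain computed
  alone and in complex with the DNA chains, *and* unbound RASA > 5%.
  RASA is ASA as a percentage of the residue type's reference maximum ASA.
* **Distance rule.** Minimum heavy-atom distance to any DNA heavy atom
  strictly below 5 Å.

The union maximizes recall of experimentally mutated residues; the
intersection is one config key away (`interface_policy`). All thresholds
(`delta_asa_min`, `rasa_min_pct`, `distance_cutoff`) live in `RunConfig`
with the defaults above.

## Solvent accessibility and exposure

SASA is computed by the Shrake–Rupley method with a deterministic
generalized-spiral (Fibonacci) point lattice — 960 points per atom by
default, probe radius 1.4 Å, heavy atoms only. The lattice has no random
component, so results are bit-reproducible; doubling the point count moves
per-residue ASA by well under 2% on the shipped fixtures. A Lee–Richards
slicing engine (the algorithm behind Naccess) is deliberately not
implemented: the two algorithms agree closely at this point density, and
the RASA > 5% interface gate is robust to the difference. vdW radii and
the per-residue-type reference ASA table (theoretical maximum ASA in an
extended context, Tien et al. 2013) ship as editable plain-text data files
whose headers record their sources; swap in tripeptide empirical values if
Naccess-compatible denominators are preferred.

Half-sphere exposure splits the ≤ 13 Å CA neighbourhood of a residue at
the plane through CA normal to the CA→CB direction (pseudo-CB from N/CA/C
geometry for glycine); contact number is the same count unsplit, so
`hse_up + hse_down = contact_number` exactly at matched radius. 13 Å is
the convention of the original half-sphere-exposure work; the radius is a
parameter.

Residue depth is approximated from the accessible point cloud retained by
the SASA computation: atom depth = (distance to the nearest accessible
surface point) − (atom vdW radius), averaged over the residue's heavy
atoms. A fully exposed atom's nearest accessible point lies on its own
extended sphere, so the measure's floor is the probe radius (≈1.4 Å);
buried atoms score deeper. This avoids an external triangulated-surface
engine and is accurate enough for feature ranking, though it is not the
classic molecular-surface depth of Chakravarty–Varadarajan.

## Residue interaction network

Nodes are protein residues (all of them, isolated nodes allowed) plus every
nucleotide participating in at least one contact. Six interaction types
are detected geometrically, each threshold configurable:

| type | criterion | default |
|---|---|---|
| hydrogen bond | N/O/S donor to N/O acceptor heavy-atom distance | ≤ 3.5 Å |
| van der Waals | heavy-atom pair within vdW radii sum + slack, only when no tighter type applies | +0.5 Å |
| disulfide | CYS SG–SG | ≤ 2.5 Å |
| salt bridge | basic N (Lys NZ, Arg NH1/NH2/NE, His ND1/NE2) to acidic/phosphate O | ≤ 4.0 Å |
| π–π | aromatic ring centroid distance (PHE/TYR/TRP/HIS, DNA base rings) | ≤ 5.5 Å |
| π–cation | ring centroid to cationic N | ≤ 6.0 Å |

These are standard literature values; orientation angles for π systems are
not applied (distance-only criterion). Parallel typed contacts between one
pair collapse to a single edge weighted by the minimum contact distance,
with the type labels retained.

Ten centrality features are computed per node. Which measures use the
distance weights was an open design choice; the convention here is:

| weighted (distance as path length / resistance) | unweighted adjacency |
|---|---|
| closeness, betweenness, eccentricity, flow closeness | degree, clustering, square clustering, eigenvector, Katz, average neighbour degree |

Disconnected graphs are handled per component; closeness and flow
closeness carry the `(k−1)/(n−1)` component-size scaling. Flow closeness
(information centrality) treats edge distance as electrical resistance and
is computed from the component Laplacian pseudoinverse,
`C(v) = (k−1) / Σ_w R_eff(v, w)`. Katz uses α = 0.1, β = 1; when a
component's spectral radius would make the series diverge, α shrinks
automatically to 0.9/λ_max. Singleton conventions: closeness 0,
eccentricity 0, eigenvector 1, Katz β, flow closeness 0.

## Features

The `structure_only` profile computes ≥ 20 named feature columns with no
external files: the ten `rin_*` centralities, ASA/RASA, HSE up/down,
contact number, residue depth, mean heavy-atom B-factor, hydrogen-bond
count (hbond edges incident to the residue in the RIN), local structural
entropy, the eight physicochemical scales, and the BLOSUM62 wild-type row
plus wild-type→mutant score. Mutation-aware features are limited to BLOSUM
and physicochemical deltas; structural features describe the wild type.

* **BLOSUM62** comes from biopython's published matrix.
* **Physicochemical scales** (helix propensity, polarity, hydrophilicity,
  average accessible area, hydrophobic-moment weights, flexibility,
  hydrophobicity, polarizability) ship as eight one-property text files
  with their sources in the headers; they are swappable, and which exact
  scales to use was an open choice.
* **Conservation** is the Jensen–Shannon divergence between a column's
  amino-acid distribution and a BLOSUM-style background, λ = 0.5,
  normalized to [0, 1]; gap fraction is reported separately and window
  smoothing is off by default.
* **Local structural entropy** averages 4-mer word values over the up-to-4
  windows covering a position. No canonical public word table exists, so
  the default is a clearly-synthetic compositional toy (per-letter
  flexibility mean); real tables load from a two-column text file.
* Features produced in practice by external predictors (PSI-BLAST PSSM,
  DSSP secondary structure/accessibility/torsions, secondary-structure and
  RSA predictor tables) are *read, not recomputed*: the `full` profile
  joins their native file dialects by residue number, keeps unmatched
  residues explicitly missing, and treats a <50% match rate as a hard
  error because it almost always means a numbering mismatch.

Assembly is deterministic (stable registry order, byte-identical output
for identical input) and every column carries a provenance tag.

## Dataset rules

Hot spot ⇔ interface residue with ΔΔG ≥ 1.0 kcal/mol, inclusive; the sign
convention is positive = destabilizing, and tables using the opposite
convention must be pre-negated. Wild-type identities are validated against
the structure; mismatches exclude the record with a logged reason rather
than aborting the run.

Redundancy removal replaces CD-HIT with an explicit greedy longest-first
clustering: a sequence joins the first cluster whose representative shares
global-alignment identity strictly above 40% (match +1, mismatch 0, linear
gap −1; identity = matches / alignment length). CD-HIT's k-mer screening
heuristics only matter for throughput, not membership, at this scale.
Clustering operates on protein chains; samples of dropped chains drop with
them.

Benchmark/independent splits are assigned at the whole-complex level so no
structure contributes samples to both sides. The optional balance search
keeps, among seeded random assignments, the one with the most even
hot/non-hot benchmark counts.

## Evaluation and the E_c criterion

ACC, SEN, SPE, PRE, F1 and MCC are the standard confusion-matrix closed
forms; any zero denominator yields 0 with a flag rather than an exception.
AUC is the Mann–Whitney statistic (concordant + half-tied pairs over
positive×negative pairs). Cross-validation is stratified k-fold (k = 10),
repeated (30 repeats for final reporting, 3 during feature selection as a
cost control — full fidelity is one config knob away); each repeat
reshuffles with `seed + repeat`. Per-fold metrics are averaged, not pooled.
Stratification is a deliberate choice: it stabilizes SEN/SPE at the
~180-sample scale this protocol targets.

The selection criterion is

    E_c = mean over repeats of ( mean over folds of (ACC + SEN + SPE + MCC + AUC) )

bounded in [−1, 5]; a perfect classifier scores 5.0. The inner quantity is
the *sum* of the five metrics — only the relative ordering of E_c matters
to backward selection, so sum versus mean is a monotone rescaling.
Optionally each fold's test set is augmented with an external (independent)
table before scoring, the combined-test selection protocol.

Feature F-scores use the standard discrimination form
`((μ₊−μ)² + (μ₋−μ)²) / (σ²₊ + σ²₋)` with class sample variances; features
constant in both classes score 0 with a flag, and rank ties break by name.

## Selection and the stacked ensemble

Sequential backward selection evaluates, per round, every leave-one-out
subset of the current feature set under identical fold seeds (paired
comparison), adopts the best subset only on strict E_c improvement, and
stops otherwise — ties stop selection, which avoids plateau walks. The
adopted-subset E_c sequence is therefore strictly increasing.

The ensemble stacking classifier (ESC) feeds the class-1 probabilities of
three base learners into a logistic-regression meta-model. Meta-features
are out-of-fold probabilities from an internal stratified 5-fold scheme —
naive in-sample stacking visibly overfits at n ≈ 180 — after which the
base learners are refit on all rows. The reference trio is three gradient
boosting variants (XGBoost, LightGBM, sklearn gradient tree boosting) with
library defaults and pinned seeds; no hyperparameter search is performed.
Base learners are pluggable behind a fit/predict_proba contract, and a
lightweight sklearn trio (`fast_base_specs`: boosted stumps, logistic
regression, naive Bayes) backs quick runs and most of the test suite. The
ensemble vote classifier (EVC) is the unweighted mean of member
probabilities. Classification threshold is fixed at 0.5. Prediction binds
columns by name: missing features are an error, extras a warning.

## Synthetic fixtures

`make_toy_complex` builds an ideal α-helix (2.3 Å radius, 1.5 Å rise,
100°/residue; N/CA/C/O/CB atoms) beside an idealized straight B-form-like
duplex (phosphate, sugar and base-ring atoms, 3.4 Å rise, no helical
twist), positioned by bisection so the closest heavy-atom gap equals the
requested value exactly. Ground-truth interface residues are recorded from
the generator's own all-pairs distance scan. Dedicated two-residue
fixtures exercise the disulfide, salt-bridge, π–π and π–cation detectors.
`make_planted_table` draws informative columns from class-conditional
normals separated by a chosen standardized shift and noise columns from
the standard normal; `make_mutation_table` emits rows that reference real
residues of the toy complex and round-trip through validation with zero
errors. All generators are pure functions of (spec, seed).

What the fixtures do **not** emulate: side-chain rotamers, DNA helical
twist, crystallographic disorder, correlated real-data features, and any
physically meaningful energetics. Passing tests therefore demonstrate that
the geometry detectors, network measures, selection dynamics and ensemble
plumbing behave correctly — not that the default feature set reaches any
particular accuracy on curated experimental mutation data, which requires
user-supplied structures, mutation tables and external predictor files.

## Problem sizes and numerical notes

The test suite and the acceptance script run the pipeline at deliberate
desk scale: 12-residue helices with 8-bp duplexes, planted tables of
n = 200 with 3 informative + 17 noise columns (shift 1.5 for selection
studies, 3.0 for separability checks), selection CV at 3 repeats × 10
folds, and a linear-discriminant evaluator inside the 20-seed selection
study (the boosting ESC is exercised separately in the ensemble checks).
Oracle agreement for the ten centralities is checked on 50 random graphs
of ≤ 8 nodes at 1e-6, where exhaustive path enumeration and per-pair
current-flow solves remain exact and fast.

Degenerate inputs: residues without CA (or without a CB direction) get
missing exposure values with warnings rather than aborting; unknown
elements fall back to a 1.8 Å radius with a warning; empty structures,
empty alignment columns, single-class labels and oversized fold counts are
explicit errors.

## Known limitations

* ΔASA in the interface rule is interpreted in Å² (the natural unit for an
  area difference).
* The SASA point-cloud depth underestimates depth gradients in narrow
  clefts relative to triangulated molecular surfaces.
* Six interaction types are detected by distance only; no angular terms.
* CD-HIT word-filter behaviour is not reproduced, only its clustering
  semantics.
* The model archive is version-gated but joblib-based: load archives only
  from trusted sources.
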