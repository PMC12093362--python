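# Methods

`qsarshift` implements a complete evaluation pipeline for the question:
*how well do binary bioactivity (QSAR) classifiers trained on one data
source transfer to another, and what does the chemistry of the two
sources say about it?* The archetypal setting is a public database
extract (ChEMBL-like) versus an in-house pharmaceutical collection:
different assay panels, different chemistry, opposite class skews.
Because matched public/proprietary data cannot be redistributed, the
package ships a synthetic two-domain study generator with the same
statistical structure, and every claim the test suite makes is made on
that generator.

## Curation model

Potency measurements (IC50 or Ki, pooled as interchangeable replicates)
are binarized at **10 µM**: active iff potency ≤ 10 µM. The tie is
inclusive on the active side so that unit-conversion rounding can never
flip a label. Structures are standardized before anything else: largest
organic fragment (salt stripping), charge neutralization, stereochemistry
removal; the stereo-free InChI of the result is the identity key used
for duplicate merging, leakage filtering and delta-set construction.
Inputs without a carbon atom are rejected as non-organic.

Replicates that disagree across the threshold are reconciled
asymmetrically by source:

* **public-like** — the compound is removed (public aggregation mixes
  heterogeneous assays; a conflict is unresolvable noise);
* **proprietary-like** — the compound is called *active* (consistent
  in-house data management is assumed, and in off-target profiling a
  false positive is cheaper than a missed liability).

Relation qualifiers are used only where they are safe: `>` above the
threshold is classifiable inactive, `<` at or below it active; any other
qualified measurement is excluded and logged. A curated set is eligible
for modelling only with **≥ 250 compounds** and **≥ 15% minority
class**; both rules are checked on the final set (after conflict
removal) and a failed set becomes a rejection record carrying the
observed counts. Every removal, merge and rejection is written to a
curation log with a reason code — the counts are audit outputs, not
noise.

## Representations

* **Hashed circular (Morgan) fingerprints**, radius 2, 2048 bits,
  binary. Used for Tanimoto similarity, Butina clustering,
  nearest-neighbour diagnostics and similarity-filtered mixing.
* **E-state vector**: RDKit's electrotopological-state index sums over
  its 79 atom types — a fixed 79-dimensional vector. This stands in for
  the proprietary Molconn-Z E-state set of the same nominal width; the
  exact feature list differs, and all downstream code treats descriptor
  width as data-driven.
* **Embedding vectors**: any compound-key → fixed-width numeric table
  (e.g. 512-wide translation-autoencoder embeddings) can be loaded as a
  provider. A missing key is a miss, never a zero vector; compounds
  without vectors are dropped with a log entry and the dataset view is
  narrowed to match. There is no imputation anywhere.
* **Physicochemical profile**: molecular weight, H-bond donors and
  acceptors, heavy atoms, rotatable bonds, TPSA, and `logp_proxy` —
  computed Crippen logP standing in for an ionization-aware logD at
  pH 7.5, named to make the substitution explicit.

## Splitting and nested cross-validation

Tanimoto similarity and **Butina sphere-exclusion clustering** are
implemented from first principles (vectorized over packed bit rows;
float64 keeps the 0/1 dot products exact, so results match scalar set
arithmetic bitwise). The clustering threshold is a *similarity* of
**0.230** (equivalently a distance cutoff of 0.770 in the usual Butina
parameterization). Centroid ties on the neighbour count go to the lowest
input index, making the procedure fully deterministic; the suite checks
it against an independent set-based reference.

Folds come in two schemes:

* **random** — seeded shuffle per class, then round-robin dealing: class
  ratios per fold within one compound of the even share (unstratified
  folds can produce single-class inner folds at 15% minority, which
  breaks MCC);
* **cluster** — Butina clusters packed whole into folds, largest first
  into the currently smallest fold. No cluster ever spans folds; if a
  fold would remain empty the split is refused with both counts named.

Model selection is a **5-fold inner / 9-fold outer nested CV**. Inner
folds tune over fixed, deliberately non-extensive grids (random forest:
n_estimators ∈ {50,100,200} × max_depth ∈ {None,10,20}; gradient-boosted
trees: n_estimators ∈ {50,100,200} × max_depth ∈ {3,5,7}; SVM: C ∈
{0.1,1,10} × kernel ∈ {linear,rbf}), scored by mean inner-validation
**MCC** with ties broken by grid order. The final model is retrained on
the full set with the **mode** of the nine outer selections — less prone
to overfitting than taking the single best score, and the odd outer-fold
count keeps the mode well defined more often; residual ties resolve by
higher mean outer-test MCC, then grid order. Inner seeds derive
deterministically from the run seed and fold index. The SVM is wrapped
with in-pipeline feature standardization (fit on the training portion
only) and refuses training sets above a configurable cap (default
20 000), since kernel-SVM cost grows too fast with n.

All eight reported metrics (sensitivity, specificity, balanced accuracy,
accuracy, PPV, NPV, F-measure, MCC) are computed from the confusion
table by their textbook formulas. A zero denominator yields NaN — never
a silent 0 — except the MCC, which is 0 by convention when any factor
under the root vanishes (a degenerate predictor carries no correlation);
that substitution is logged.

## Cross-domain transfer and bias

A frozen final model from one domain is applied to the other domain's
curated set after **InChI leakage filtering**: any test compound whose
standardized InChI occurs in the training set is removed (individually
logged), and `evaluate_cross` refuses to score a test set that still
intersects the model's training InChIs. No refitting or recalibration
happens at transfer time. The confusion table is then classified for
directional bias: `overpredicts_actives` iff FP − FN > 5% of the test
size, `overpredicts_inactives` for the mirror image, else `balanced`.
The 5% margin keeps noise from being labelled as bias; it is a package
choice, configurable in one place.

## Chemical-space diagnostics

* **Nearest-neighbour mean Tanimoto**: for each query compound the
  maximum similarity over the reference set, averaged. Asymmetric by
  construction; the default direction asks how well the public-like set
  covers the proprietary-like one. Equal sets give exactly 1.
* **2-D UMAP embedding** (n_neighbors 15, min_dist 0.1, 2 components,
  mandatory seed) over E-state descriptors by default; compounds shared
  between domains are flagged as a third plotting category, and delta
  sets (each domain minus the shared InChIs) can be built for both
  directions.
* **Property comparison**: per property, medians and quartiles per set
  plus a robust standardized shift, (median_B − median_A)/(pooled
  IQR/1.349). Identical sets give shift 0 everywhere.

These are diagnostics of data-set relatedness only. The package
deliberately does *not* assert that high similarity predicts good
transfer — the diagnostics-decoupling study constructs the
counterexample (high NN similarity, flipped activity rule, poor cross
MCC).

## Mixed training sets

Starting from a proprietary-like base set, public compounds are added
under three nested strategies: (a) same target only; (b) additionally
matching the base set's assay format; (c) additionally requiring maximum
Tanimoto similarity to the base set ≥ 0.230. Public sources rarely
annotate the format explicitly, so it is derived: entries with assay
type Binding/ADME/Toxicity are retained, and a cell-line annotation
marks cell-based, its absence cell-free; other assay types are excluded
and logged. On an InChI collision the base compound (and its label)
wins. By construction the member sets nest c ⊆ b ⊆ a, and every base
compound appears exactly once in every compilation.

## The synthetic two-domain generator

Molecules are built by attaching two substituents (from a 14-fragment
vocabulary) to one of 16 scaffold templates, each combining ring systems
used (nearly) uniquely across the list. Ground-truth potency follows

    log10 potency [µM] = 1.8 − 2.5·[pharmacophore present]
                         + N(0, 0.4) per scaffold + N(0, 0.5) per compound

where the pharmacophore is one of three activity-conferring fragments
(primary sulfonamide, carboxylic acid, methanesulfonamido) detected by
SMARTS, carried by a controlled 42% of each scaffold's library slice
(stratified sampling, not binomial). These values were fixed once so
that (i) labels are learnable from structure, (ii) the scaffold term
makes transfer across scaffold-disjoint domains genuinely harder, and
(iii) a library of ~180 compounds per scaffold can supply both an
80%-active public draw and an 80%-inactive proprietary draw for
essentially every seed.

The sampler then draws the two domains: exact ground-truth class
fractions (defaults 0.8 active public-like, 0.2 active
proprietary-like), scaffold pools sharing a controllable fraction of
scaffolds, an exact number of identical compounds copied between domains
(default 10%), replicate measurements with log-normal noise (sd 0.3
log units), a planted fraction of threshold-straddling replicate
conflicts in both domains (default 5% of replicated compounds), and
assay-format structure (explicit tags in the proprietary-like table;
assay-type codes plus cell-line names in the public-like table). An
optional switch flips the pharmacophore effect in the proprietary
domain (for the decoupling study), and another injects label noise into
one derived public format (for the mixing study). Ground truth is
written to a separate table that no pipeline stage reads.

What the generator does *not* emulate: real measurement-type systematic
offsets (IC50 vs Ki), assay-to-assay batch structure, tautomerism,
property distributions of real screening decks, and activity cliffs
sharper than the latent Gaussian allows. Passing tests therefore show
that the pipeline's *mechanics and qualitative findings* (signal
recovery, null behaviour, skew-driven bias, overlap-driven transfer gap,
format-noise filtering) are correct on data with this structure — not
that any particular real-world transfer will behave the same way.

A designated fixture vocabulary (`FIXTURE_SCAFFOLD_PERMUTATION`,
`FIXTURE_SUBSTITUENT_IDS`: six scaffolds split into two groups, small
substituents only) is shipped for tests that need *strictly* separable
scaffold families: every cross-group product pair sits below Tanimoto
0.230, verified exhaustively. With the full substituent vocabulary such
strict separation is unattainable — two compounds on different scaffolds
sharing both substituents always retain a similarity floor — which is
itself a realistic feature of drug-like libraries.

## Numerical and design choices

* Similarity matrices in float64: intersections and unions are exact
  integers, so vectorized and scalar similarities agree bitwise.
* All RNGs are `numpy` Generators seeded from one run seed via hashed
  derivation; identical config + seed reproduces every output byte for
  byte (study tables, folds, CV results, embeddings).
* Simulation studies default to 300 compounds per domain and the SVM
  family with its full grid — at these sizes the SVM is the fastest of
  the three families by an order of magnitude, and the studies'
  conclusions concern the data sets, not the classifiers. The acceptance
  script averages 3 seeds; the test suite's property checks use 10.
* Degenerate inputs fail loudly: empty fingerprint pairs warn and score
  0, empty datasets refuse to fit, an unfillable fold count names both
  numbers, an infeasible class draw names the deficit.

## Known limitations

* The E-state feature list approximates, not reproduces, Molconn-Z; no
  attempt is made to guess the proprietary feature set.
* `logp_proxy` ignores ionization; shifts in that column are not logD
  shifts.
* Butina clustering materializes the full similarity matrix (O(n²)
  memory) — fine at study scale, not for millions of compounds.
* Tautomer canonicalization is limited to charge neutralization.
* The outer-CV repeat count is a config knob (default 1); repeated-CV
  ensembles are not aggregated beyond the mode rule.
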