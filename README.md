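# qsarshift

Cross-source evaluation of binary bioactivity (QSAR) classifiers: what
happens when a model trained on one bioactivity data source — say a
public ChEMBL-like extract — is applied to compounds from another, such
as an in-house pharmaceutical collection?

The package is for computational chemists and ML practitioners who work
with bioactivity data from heterogeneous sources. It provides, as a
tested library plus CLI:

* **Curation** of per-target binary data sets from activity tables:
  structure standardization (salt stripping, neutralization, stereo
  removal), classification at the 10 µM IC50/Ki threshold, asymmetric
  replicate-conflict rules per source, and the ≥250-compound /
  ≥15%-minority eligibility gate — every removal logged.
* **Representations**: Morgan (radius-2, 2048-bit) fingerprints, a
  79-dimensional E-state vector, loadable embedding-vector tables, and
  a seven-property physicochemical profile.
* **Nested cross-validation** (5-fold inner, 9-fold outer) for random
  forest, gradient-boosted trees and SVM over fixed grids, selected by
  MCC, with the final model retrained on the *mode* of the outer-fold
  hyperparameter selections; random (class-stratified) and
  cluster-integrity (from-scratch Butina, Tanimoto ≥ 0.230) fold
  schemes.
* **Cross-domain transfer** of frozen models with InChI leakage
  filtering and a directional over-prediction diagnosis (FP vs FN).
* **Chemical-space diagnostics**: nearest-neighbour mean Tanimoto
  between sources, seeded 2-D UMAP maps, robust property-distribution
  comparison.
* **Mixed training sets** compiled from a proprietary-like base plus
  public data under three nested strategies (target only; + assay
  format; + Tanimoto ≥ 0.230), with derived cell-based/cell-free
  formats for public rows.
* A **synthetic two-domain study generator** that emulates the
  public/proprietary structure (opposite class skews, controllable
  scaffold and identity overlap, replicate conflicts, assay-format
  annotations), so the entire pipeline is testable without proprietary
  data.

The central metric is the Matthews correlation coefficient,

    MCC = (TP·TN − FP·FN) / √((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

reported alongside sensitivity, specificity, balanced accuracy,
accuracy, PPV, NPV and F-measure.

## Worked example

```python
from qsarshift import (GeneratorSpec, generate_study, build_target_dataset,
                       RunConfig, compute_descriptor_matrix, run_nested_cv,
                       retrain_final, cross_domain_transfer)

spec = GeneratorSpec(seed=1, n_per_domain=300)        # two-domain study
study = generate_study(spec)

config = RunConfig(seed=1)
public = build_target_dataset(study.public_rows, "TGT1", "public_like", config)
proprietary = build_target_dataset(study.proprietary_rows, "TGT1",
                                   "proprietary_like", config)
print(f"public: {len(public)} compounds, {public.n_active()} active")
print(f"proprietary: {len(proprietary)} compounds, {proprietary.n_active()} active")

X = compute_descriptor_matrix(public, "estate_like")
cv = run_nested_cv(public, X, "svm", "random", config=config)
print(f"within-domain mean outer MCC: {cv.mean_outer_mcc():.3f}")
print(f"final hyperparameters: {cv.final_hyperparams}")

model = retrain_final(public, X, "svm", cv.final_hyperparams, seed=1)
report = cross_domain_transfer(
    model, public, proprietary,
    lambda ds: compute_descriptor_matrix(ds, "estate_like"))
print(f"cross-domain MCC: {report.report.mcc:.3f} "
      f"(FP={report.report.counts.fp}, FN={report.report.counts.fn}, "
      f"bias: {report.bias_direction})")
```

prints

```
public: 288 compounds, 227 active
proprietary: 300 compounds, 79 active
within-domain mean outer MCC: 0.729
final hyperparameters: {'C': 0.1, 'kernel': 'linear'}
cross-domain MCC: 0.223 (FP=103, FN=14, bias: overpredicts_actives)
```

Reading it: within its own (majority-active) domain the model is a good
classifier (MCC 0.73 out of fold), but applied to the majority-inactive
domain its MCC collapses to 0.22, and the error structure is one-sided —
103 false actives against 14 false inactives. A model trained on
active-skewed data over-predicts actives elsewhere; the mirrored
experiment (train on the inactive-skewed domain) over-predicts
inactives. Chemical-space overlap modulates the size of the drop but, as
the `diagnostics-decoupling` study shows, high structural similarity
between sources does not by itself guarantee transferability.

The same stages are scriptable from the shell:

```bash
qsarshift simulate --seed 1 --out study/
qsarshift curate --table study/public_activity.csv --target TGT1 \
    --domain public_like --seed 1 --out curated/
qsarshift train --table study/public_activity.csv --target TGT1 \
    --domain public_like --algorithm svm --seed 1 --out model/
qsarshift report --study bias --seed 1 --out reports/
```

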