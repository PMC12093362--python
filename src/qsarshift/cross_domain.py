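"""Frozen-model transfer between data domains, with leakage filtering
and over-prediction bias diagnosis.

Before a model trained on one source is scored on the other source's
data set, every test compound whose stereo-free InChI occurs in the
training set is filtered out, so the cross-domain estimate is never
inflated by shared compounds. The confusion table of the transfer is
then classified for directional bias: a clear excess of false positives
means the model over-predicts actives on the foreign domain, a clear
excess of false negatives means it over-predicts inactives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .curation import ClassifiedDataset
from .descriptors import DescriptorMatrix
from .metrics import ConfusionCounts, MetricsReport, evaluate_predictions
from .nested_cv import ModelBundle, labels_to_int

BIAS_ACTIVES = "overpredicts_actives"
BIAS_INACTIVES = "overpredicts_inactives"
BIAS_BALANCED = "balanced"

#: A directional bias call requires |FP - FN| above this fraction of the
#: test-set size; smaller imbalances are reported as balanced.
BIAS_MARGIN_FRACTION = 0.05


class LeakageError(RuntimeError):
    """The test set still shares compounds with the model's training set."""


@dataclass
class CrossEvalReport:
    train_domain: str
    test_domain: str
    target_id: str
    n_test_before: int
    n_removed_leakage: int
    n_test_after: int
    report: MetricsReport
    bias_direction: str

    def to_row(self) -> dict:
        row = self.report.to_row()
        row.update(
            train_domain=self.train_domain,
            test_domain=self.test_domain,
            target=self.target_id,
            n_test_before=self.n_test_before,
            n_removed_leakage=self.n_removed_leakage,
            n_test_after=self.n_test_after,
            bias_direction=self.bias_direction,
        )
        return row


def filter_leakage(
    test_set: ClassifiedDataset, train_set: ClassifiedDataset
) -> tuple[ClassifiedDataset, list[str]]:
    """Drop test compounds whose InChI occurs in the training set.

    A pure set operation: idempotent and independent of member order.
    Returns the filtered set and the removed compound keys (logged
    individually in the returned set's curation log).
    """
    train_inchis = train_set.inchis
    keep, removed = [], []
    for i, (rec, _) in enumerate(test_set.members):
        if rec.inchi in train_inchis:
            removed.append(rec.compound_key)
        else:
            keep.append(i)
    filtered = test_set.subset(keep)
    filtered.curation_log = list(test_set.curation_log) + [
        (key, "removed", "train/test overlap (leakage)") for key in removed
    ]
    return filtered, removed


def classify_bias(counts: ConfusionCounts, n_test: int) -> str:
    """Directional over-prediction call from the confusion table."""
    margin = BIAS_MARGIN_FRACTION * n_test
    if counts.fp - counts.fn > margin:
        return BIAS_ACTIVES
    if counts.fn - counts.fp > margin:
        return BIAS_INACTIVES
    return BIAS_BALANCED


def evaluate_cross(
    bundle: ModelBundle,
    test_set: ClassifiedDataset,
    matrix: DescriptorMatrix,
    n_test_before: int | None = None,
    n_removed_leakage: int = 0,
    train_domain: str = "foreign",
) -> CrossEvalReport:
    """Score a frozen model on a (leakage-filtered) foreign data set.

    The model is never refit or recalibrated. Raises
    :class:`LeakageError` if any test InChI is still present in the
    bundle's training set, and a ``ValueError`` on a descriptor-provider
    mismatch.
    """
    if bundle.provider_tag != matrix.provider_tag:
        raise ValueError(
            f"descriptor provider mismatch: model uses {bundle.provider_tag!r}, "
            f"matrix is {matrix.provider_tag!r}"
        )
    keys = [rec.compound_key for rec, _ in test_set.members]
    if keys != list(matrix.compound_keys):
        raise ValueError("descriptor matrix is not aligned to the test set")
    overlap = test_set.inchis & bundle.train_inchis
    if overlap:
        raise LeakageError(
            f"{len(overlap)} test compounds occur in the training set; "
            "run filter_leakage first"
        )
    y = labels_to_int(test_set.labels)
    pred = bundle.predict(matrix.matrix)
    report = evaluate_predictions(
        y,
        pred,
        context={
            "target": test_set.target_id,
            "train_domain": train_domain,
            "test_domain": test_set.domain,
            "algorithm": bundle.algorithm_tag,
            "descriptor": bundle.provider_tag,
        },
    )
    return CrossEvalReport(
        train_domain=train_domain,
        test_domain=test_set.domain,
        target_id=test_set.target_id,
        n_test_before=n_test_before if n_test_before is not None else len(test_set),
        n_removed_leakage=n_removed_leakage,
        n_test_after=len(test_set),
        report=report,
        bias_direction=classify_bias(report.counts, len(test_set)),
    )


def cross_domain_transfer(
    bundle: ModelBundle,
    train_set: ClassifiedDataset,
    test_set: ClassifiedDataset,
    featurize,
) -> CrossEvalReport:
    """Convenience wrapper: filter leakage, featurize, evaluate.

    ``featurize`` maps a ClassifiedDataset to an aligned DescriptorMatrix
    with the bundle's provider.
    """
    n_before = len(test_set)
    filtered, removed = filter_leakage(test_set, train_set)
    matrix = featurize(filtered)
    return evaluate_cross(
        bundle,
        filtered,
        matrix,
        n_test_before=n_before,
        n_removed_leakage=len(removed),
        train_domain=train_set.domain,
    )


def bias_diagnostic(report: CrossEvalReport) -> dict:
    """Compact summary of the over-prediction direction of a transfer."""
    c = report.report.counts
    return {
        "target": report.target_id,
        "train_domain": report.train_domain,
        "test_domain": report.test_domain,
        "fp": c.fp,
        "fn": c.fn,
        "fp_minus_fn": c.fp - c.fn,
        "bias_direction": report.bias_direction,
        "mcc": report.report.mcc,
    }
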