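"""Nested cross-validation with mode-of-hyperparameters final retraining.

An outer loop (default 9 folds) estimates generalization; for each outer
training portion an inner loop (default 5 stratified folds) scores every
grid point by mean validation MCC and picks the best. The final model is
retrained on the full data set with the hyperparameter combination
selected most often across the outer folds — the mode, not the single
highest-MCC combination, which is less prone to overfitting the search.
An odd outer fold count keeps the mode well defined more often.

Three classifier families are supported behind one fit/predict contract:
random forest (rf), gradient-boosted trees (xgb) and a support-vector
classifier (svm, with feature standardization inside the model pipeline
so folds never leak scaling statistics).
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .config import RunConfig
from .curation import ACTIVE, ClassifiedDataset
from .descriptors import DescriptorMatrix, Fingerprint
from .metrics import MetricsReport, evaluate_predictions
from .splitting import ClusterAssignment, FoldAssignment, make_folds

ALGORITHMS = ("rf", "xgb", "svm")

#: Hyperparameter grids, in selection order (ties go to the earlier entry).
HYPERPARAM_GRIDS: dict[str, list[dict[str, Any]]] = {
    "rf": [
        {"n_estimators": n, "max_depth": d}
        for n in (50, 100, 200)
        for d in (None, 10, 20)
    ],
    "xgb": [
        {"n_estimators": n, "max_depth": d}
        for n in (50, 100, 200)
        for d in (3, 5, 7)
    ],
    "svm": [
        {"C": c, "kernel": k} for c in (0.1, 1, 10) for k in ("linear", "rbf")
    ],
}


def make_estimator(algorithm_tag: str, params: dict[str, Any], seed: int):
    """Build an unfitted classifier for one grid point."""
    if algorithm_tag == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm_tag == "xgb":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
            **params,
        )
    if algorithm_tag == "svm":
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(random_state=seed, **params))]
        )
    raise ValueError(f"unknown algorithm {algorithm_tag!r}")


def labels_to_int(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if lbl == ACTIVE else 0 for lbl in labels], dtype=int)


@dataclass
class ModelBundle:
    """A fitted classifier plus the provenance needed to reuse it safely."""

    estimator: Any
    algorithm_tag: str
    provider_tag: str
    hyperparams: dict[str, Any]
    seed: int
    dataset_hash: str
    train_inchis: frozenset[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)

    def metadata(self) -> dict[str, Any]:
        return {
            "algorithm": self.algorithm_tag,
            "descriptor_provider": self.provider_tag,
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "dataset_hash": self.dataset_hash,
            "n_train": len(self.train_inchis),
        }


@dataclass
class OuterFoldRecord:
    fold: int
    selected_hyperparams: dict[str, Any]
    report: MetricsReport
    inner_assignment: dict[str, int]  # compound_key -> inner fold, train side only
    test_keys: list[str]


@dataclass
class NestedCVResult:
    algorithm_tag: str
    provider_tag: str
    scheme: str
    seed: int
    outer_records: list[OuterFoldRecord]
    final_hyperparams: dict[str, Any]
    fold_assignment: FoldAssignment
    repeats: int = 1

    def outer_mccs(self) -> list[float]:
        return [r.report.mcc for r in self.outer_records]

    def mean_outer_mcc(self) -> float:
        return float(np.mean(self.outer_mccs()))

    def to_rows(self) -> list[dict[str, Any]]:
        rows = []
        for r in self.outer_records:
            row = r.report.to_row()
            row.update(
                fold=r.fold,
                scheme=self.scheme,
                algorithm=self.algorithm_tag,
                descriptor=self.provider_tag,
                selected=str(r.selected_hyperparams),
            )
            rows.append(row)
        return rows


def dataset_hash(dataset: ClassifiedDataset) -> str:
    blob = "\n".join(sorted(rec.inchi for rec, _ in dataset.members)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class SVMSizeError(RuntimeError):
    """Kernel-SVM fits are refused above the configured training size."""


def _check_svm_cap(algorithm_tag: str, n: int, config: RunConfig) -> None:
    if algorithm_tag == "svm" and n > config.svm_max_train_size:
        raise SVMSizeError(
            f"svm fit refused: {n} training compounds exceeds the configured "
            f"cap of {config.svm_max_train_size}"
        )


def inner_select(
    X: np.ndarray,
    y: np.ndarray,
    algorithm_tag: str,
    grid: Sequence[dict[str, Any]],
    k_inner: int,
    seed: int,
    config: RunConfig | None = None,
) -> tuple[dict[str, Any], dict[int, int]]:
    """Pick the grid point with the best mean inner-validation MCC.

    Returns the winning combination and the inner fold of every training
    index (for leakage audits). Ties are broken by grid order.
    """
    config = config or RunConfig()
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("inner selection needs both classes present")

    # stratified inner folds: per-class round-robin after a seeded shuffle
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    offset = 0
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold_of[idx] = (np.arange(len(idx)) + offset) % k_inner
        offset = (offset + len(idx)) % k_inner

    _check_svm_cap(algorithm_tag, len(y), config)
    mean_mccs = []
    for params in grid:
        fold_mccs = []
        for f in range(k_inner):
            tr = fold_of != f
            va = ~tr
            if np.unique(y[va]).size == 0 or tr.sum() == 0:
                continue
            est = make_estimator(algorithm_tag, params, seed)
            est.fit(X[tr], y[tr])
            pred = np.asarray(est.predict(X[va]), dtype=int)
            fold_mccs.append(evaluate_predictions(y[va], pred).mcc)
        mean_mccs.append(float(np.mean(fold_mccs)))
    best = int(np.argmax(mean_mccs))  # argmax keeps the earliest on ties
    return dict(grid[best]), {i: int(fold_of[i]) for i in range(len(y))}


def _mode_hyperparams(
    selections: Sequence[dict[str, Any]],
    grid: Sequence[dict[str, Any]],
    outer_mccs: Sequence[float] | None = None,
) -> dict[str, Any]:
    """Mode of the outer-fold selections.

    Ties on the count are resolved by the higher mean outer-test MCC among
    the tied combinations, then by grid order.
    """
    keys = [tuple(sorted(s.items())) for s in selections]
    counts = Counter(keys)
    top = max(counts.values())
    tied = [k for k, c in counts.items() if c == top]
    if len(tied) > 1 and outer_mccs is not None:
        mean_mcc = {
            k: float(np.mean([m for kk, m in zip(keys, outer_mccs) if kk == k]))
            for k in tied
        }
        best_mcc = max(mean_mcc.values())
        tied = [k for k in tied if mean_mcc[k] == best_mcc]
    grid_keys = [tuple(sorted(g.items())) for g in grid]
    tied.sort(key=lambda k: grid_keys.index(k) if k in grid_keys else len(grid_keys))
    return dict(tied[0])


def final_hyperparams_from_selections(
    selections: Sequence[dict[str, Any]],
    grid: Sequence[dict[str, Any]],
    outer_mccs: Sequence[float] | None = None,
) -> dict[str, Any]:
    """Public wrapper over the mode rule (used by audits and tests)."""
    return _mode_hyperparams(selections, grid, outer_mccs)


def run_nested_cv(
    dataset: ClassifiedDataset,
    matrix: DescriptorMatrix,
    algorithm_tag: str,
    scheme: str,
    config: RunConfig | None = None,
    grid: Sequence[dict[str, Any]] | None = None,
    fps: Sequence[Fingerprint] | None = None,
    clusters: ClusterAssignment | None = None,
    repeat: int = 0,
) -> NestedCVResult:
    """Full nested CV for one dataset / descriptor / algorithm / scheme.

    Inner folds are always stratified-random and partition only the outer
    training portion; their seeds derive from the run seed, the repeat
    index and the outer fold index, so repeated runs are reproducible and
    distinct.
    """
    config = config or RunConfig()
    if algorithm_tag not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm_tag!r}")
    grid = list(grid) if grid is not None else HYPERPARAM_GRIDS[algorithm_tag]
    keys = [rec.compound_key for rec, _ in dataset.members]
    if keys != list(matrix.compound_keys):
        raise ValueError("descriptor matrix is not aligned to the dataset")

    y = labels_to_int(dataset.labels)
    X = matrix.matrix
    outer_seed = config.derive_seed(repeat, 0)
    folds = make_folds(
        dataset,
        k=config.k_outer,
        scheme=scheme,
        seed=outer_seed,
        fps=fps,
        threshold=config.similarity_threshold,
        clusters=clusters,
    )
    fold_idx = folds.fold_indices(keys)

    records: list[OuterFoldRecord] = []
    for f in range(config.k_outer):
        test = fold_idx == f
        train = ~test
        if test.sum() == 0:
            raise ValueError(f"outer fold {f} is empty")
        inner_seed = config.derive_seed(repeat, 1 + f)
        selected, inner_fold_of = inner_select(
            X[train],
            y[train],
            algorithm_tag,
            grid,
            config.k_inner,
            inner_seed,
            config,
        )
        est = make_estimator(algorithm_tag, selected, inner_seed)
        _check_svm_cap(algorithm_tag, int(train.sum()), config)
        est.fit(X[train], y[train])
        pred = np.asarray(est.predict(X[test]), dtype=int)
        report = evaluate_predictions(
            y[test],
            pred,
            context={
                "target": dataset.target_id,
                "domain": dataset.domain,
                "fold": f,
                "scheme": scheme,
                "algorithm": algorithm_tag,
                "descriptor": matrix.provider_tag,
            },
        )
        train_positions = np.flatnonzero(train)
        records.append(
            OuterFoldRecord(
                fold=f,
                selected_hyperparams=selected,
                report=report,
                inner_assignment={
                    keys[train_positions[i]]: inner_fold_of[i]
                    for i in range(len(train_positions))
                },
                test_keys=[keys[i] for i in np.flatnonzero(test)],
            )
        )

    final = _mode_hyperparams(
        [r.selected_hyperparams for r in records],
        grid,
        [r.report.mcc for r in records],
    )
    return NestedCVResult(
        algorithm_tag=algorithm_tag,
        provider_tag=matrix.provider_tag,
        scheme=scheme,
        seed=config.seed,
        outer_records=records,
        final_hyperparams=final,
        fold_assignment=folds,
        repeats=config.n_cv_repeats,
    )


def retrain_final(
    dataset: ClassifiedDataset,
    matrix: DescriptorMatrix,
    algorithm_tag: str,
    final_hyperparams: dict[str, Any],
    seed: int,
    config: RunConfig | None = None,
) -> ModelBundle:
    """Fit the final model on the entire data set with the chosen params."""
    config = config or RunConfig()
    if len(dataset) == 0:
        raise ValueError("cannot retrain on an empty dataset")
    keys = [rec.compound_key for rec, _ in dataset.members]
    if keys != list(matrix.compound_keys):
        raise ValueError("descriptor matrix is not aligned to the dataset")
    _check_svm_cap(algorithm_tag, len(dataset), config)
    y = labels_to_int(dataset.labels)
    est = make_estimator(algorithm_tag, final_hyperparams, seed)
    est.fit(matrix.matrix, y)
    return ModelBundle(
        estimator=est,
        algorithm_tag=algorithm_tag,
        provider_tag=matrix.provider_tag,
        hyperparams=dict(final_hyperparams),
        seed=seed,
        dataset_hash=dataset_hash(dataset),
        train_inchis=frozenset(rec.inchi for rec, _ in dataset.members),
    )
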