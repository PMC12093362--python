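"""Run configuration and logging for the cross-source QSAR pipeline.

A single :class:`RunConfig` carries every tunable that the curation,
splitting, training and chemical-space stages share, so that a whole
study is reproducible from one YAML file plus one integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("qsarshift")

DEFAULT_UMAP_PARAMS: dict[str, Any] = {
    "n_neighbors": 15,
    "min_dist": 0.1,
    "n_components": 2,
}


@dataclass(frozen=True)
class RunConfig:
    """Shared pipeline parameters.

    Parameters
    ----------
    activity_threshold_um:
        Potency cutoff in micromolar. A measurement (IC50 or Ki) at or
        below this concentration is called active.
    min_dataset_size:
        Minimum number of curated compounds for a per-target data set to
        be eligible for modelling.
    min_minority_fraction:
        Minimum fraction of the rarer class in an eligible data set.
    similarity_threshold:
        Tanimoto similarity threshold used by Butina clustering and by
        similarity-filtered training-set compilation. Expressed as a
        similarity (the equivalent Butina distance cutoff is
        ``1 - similarity_threshold``).
    k_inner, k_outer:
        Fold counts of the nested cross-validation (inner folds tune
        hyperparameters, outer folds estimate generalization).
    svm_max_train_size:
        Refuse to fit a support-vector classifier above this training-set
        size; kernel SVM cost grows too fast with n to be practical on
        very large sets.
    umap_params:
        Parameters for the 2-D manifold embedding of chemical space.
    seed:
        Base seed for every stochastic stage. Stage-level seeds are
        derived from it deterministically.
    """

    activity_threshold_um: float = 10.0
    min_dataset_size: int = 250
    min_minority_fraction: float = 0.15
    similarity_threshold: float = 0.230
    k_inner: int = 5
    k_outer: int = 9
    n_cv_repeats: int = 1
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048
    svm_max_train_size: int = 20000
    umap_params: dict[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_UMAP_PARAMS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.min_minority_fraction < 0.5):
            raise ValueError(
                f"min_minority_fraction must be in (0, 0.5), got "
                f"{self.min_minority_fraction}"
            )
        if self.k_inner < 2 or self.k_outer < 2:
            raise ValueError("k_inner and k_outer must both be >= 2")
        if not (0.0 <= self.similarity_threshold <= 1.0):
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.activity_threshold_um <= 0:
            raise ValueError("activity_threshold_um must be positive")
        if self.min_dataset_size < 1:
            raise ValueError("min_dataset_size must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for provenance logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def derive_seed(self, *offsets: int) -> int:
        """Derive a stage seed from the base seed and stage offsets.

        Deterministic, collision-resistant across stages, and kept below
        2**31 so every downstream RNG accepts it.
        """
        blob = json.dumps([self.seed, *offsets]).encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)


def setup_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler once; idempotent."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
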