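"""Shared fixtures: tiny hand-built activity tables and cached synthetic
studies (session-scoped, since library chemistry is expensive to build
once but memoized afterwards)."""

from __future__ import annotations

import numpy as np
import pytest

from qsarshift.config import RunConfig
from qsarshift.curation import ClassifiedDataset, build_target_dataset
from qsarshift.io import ActivityTableRow
from qsarshift.synthetic import GeneratorSpec, generate_study


def make_row(
    key: str,
    smiles: str,
    value_um: float,
    domain: str = "public_like",
    target: str = "TGT1",
    relation: str = "=",
    mtype: str = "IC50",
    assay_type: str | None = None,
    cell_name: str | None = None,
    assay_format: str | None = None,
) -> ActivityTableRow:
    return ActivityTableRow(
        compound_key=key,
        structure=smiles,
        measurement_type=mtype,
        value_um=value_um,
        relation=relation,
        target_id=target,
        domain=domain,
        assay_type=assay_type,
        cell_name=cell_name,
        assay_format=assay_format,
    )


def alcohol_series(n: int) -> list[str]:
    """n distinct, trivially valid structures (linear alcohols)."""
    return ["OC" + "C" * k for k in range(n)]


def eligible_dataset(
    n: int = 60, n_active: int = 24, domain: str = "public_like",
    config: RunConfig | None = None,
) -> ClassifiedDataset:
    """A curated dataset from a homologous series, sized for fast tests."""
    config = config or RunConfig(min_dataset_size=2)
    smiles = alcohol_series(n)
    rows = [
        make_row(f"K{i}", smi, 1.0 if i < n_active else 100.0, domain=domain)
        for i, smi in enumerate(smiles)
    ]
    ds = build_target_dataset(rows, "TGT1", domain, config)
    assert isinstance(ds, ClassifiedDataset)
    return ds


@pytest.fixture(scope="session")
def default_study():
    """The shipped default two-domain study at full size (seed 7)."""
    return generate_study(GeneratorSpec(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """A 300-compound-per-domain study for model-level tests (seed 11);
    ten scaffolds per domain so cluster-based folds are constructible."""
    return generate_study(
        GeneratorSpec(seed=11, n_per_domain=300, n_scaffolds=10,
                      scaffold_overlap=0.4)
    )


@pytest.fixture(scope="session")
def curated_small(small_study):
    config = RunConfig(seed=11)
    pub = build_target_dataset(
        small_study.public_rows, "TGT1", "public_like", config
    )
    prop = build_target_dataset(
        small_study.proprietary_rows, "TGT1", "proprietary_like", config
    )
    assert isinstance(pub, ClassifiedDataset)
    assert isinstance(prop, ClassifiedDataset)
    return pub, prop, config


def subset_by_keys(ds: ClassifiedDataset, keys) -> ClassifiedDataset:
    """Members whose compound key is in ``keys`` (order of the dataset)."""
    wanted = set(keys)
    idx = [i for i, (rec, _) in enumerate(ds.members)
           if rec.compound_key in wanted]
    return ds.subset(idx)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
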