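"""Molecular representations: fingerprints, E-state vectors, loadable
embeddings, and physicochemical property profiles.

Two feature families drive the models downstream: a 79-dimensional
electrotopological-state (E-state) sum vector, and externally produced
fixed-width embedding vectors loaded from a key -> vector table (the
width is data-driven; 512 is the nominal width of translation-autoencoder
embeddings). Hashed circular (Morgan, radius 2) fingerprints are kept
alongside for similarity, clustering, and similarity-filtered mixing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter

from .config import logger
from .curation import ClassifiedDataset, CompoundRecord

PROVIDER_TAGS = ("estate_like", "embedding", "fingerprint_bits")


@dataclass(frozen=True)
class Fingerprint:
    """Binary hashed circular fingerprint over a fixed bit universe."""

    compound_key: str
    bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.n_bits:
            raise ValueError("bit index outside the fingerprint universe")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


@dataclass
class DescriptorMatrix:
    provider_tag: str
    matrix: np.ndarray  # compounds x features
    feature_names: list[str]
    compound_keys: list[str]
    dropped: list[tuple[str, str]]  # (compound_key, reason)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("descriptor matrix must be 2-D")
        if self.matrix.shape[0] != len(self.compound_keys):
            raise ValueError("row count must match compound count")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count must match feature-name count")


PHYSCHEM_PROPERTIES = (
    "molecular_weight",
    "hbond_donors",
    "hbond_acceptors",
    "heavy_atoms",
    "rotatable_bonds",
    "tpsa",
    "logp_proxy",
)


@dataclass(frozen=True)
class PhyschemRecord:
    """Seven basic physicochemical properties.

    ``logp_proxy`` is a computed octanol/water logP (Crippen); it stands
    in for an ionization-aware logD and is named to make that explicit.
    """

    molecular_weight: float
    hbond_donors: int
    hbond_acceptors: int
    heavy_atoms: int
    rotatable_bonds: int
    tpsa: float
    logp_proxy: float


def _mol_from(record: CompoundRecord | str) -> Chem.Mol:
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"cannot featurize structure {smiles!r}")
    return mol


from functools import lru_cache


@lru_cache(maxsize=262144)
def _fingerprint_bits(smiles: str, radius: int, n_bits: int) -> frozenset[int]:
    mol = _mol_from(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def compute_fingerprint(
    record: CompoundRecord | str,
    radius: int = 2,
    n_bits: int = 2048,
    compound_key: str | None = None,
) -> Fingerprint:
    """Hashed circular fingerprint (radius 2, 2048 bits by default)."""
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    key = compound_key or (
        record.compound_key if isinstance(record, CompoundRecord) else str(record)
    )
    return Fingerprint(
        compound_key=key, bits=_fingerprint_bits(smiles, radius, n_bits), n_bits=n_bits
    )


@lru_cache(maxsize=262144)
def _estate_sums(smiles: str) -> tuple[float, ...]:
    mol = _mol_from(smiles)
    _counts, sums = EStateFingerprinter.FingerprintMol(mol)
    return tuple(float(v) for v in sums)


def compute_estate_vector(record: CompoundRecord | str) -> np.ndarray:
    """79-dimensional E-state index sum vector (one slot per atom type)."""
    smiles = record.canonical_smiles if isinstance(record, CompoundRecord) else record
    return np.asarray(_estate_sums(smiles), dtype=float)


def compute_physchem(record: CompoundRecord | str) -> PhyschemRecord:
    mol = _mol_from(record)
    return PhyschemRecord(
        molecular_weight=Descriptors.MolWt(mol),
        hbond_donors=Descriptors.NumHDonors(mol),
        hbond_acceptors=Descriptors.NumHAcceptors(mol),
        heavy_atoms=mol.GetNumHeavyAtoms(),
        rotatable_bonds=Descriptors.NumRotatableBonds(mol),
        tpsa=Descriptors.TPSA(mol),
        logp_proxy=Descriptors.MolLogP(mol),
    )


class EmbeddingProvider:
    """Lookup handle over a compound_key -> fixed-width vector table."""

    def __init__(self, table: dict[str, np.ndarray], dimension: int):
        self._table = table
        self.dimension = dimension

    def get(self, compound_key: str) -> np.ndarray | None:
        """The stored vector, or ``None`` (a miss signal, never zeros)."""
        return self._table.get(compound_key)

    def __contains__(self, compound_key: str) -> bool:
        return compound_key in self._table

    def __len__(self) -> int:
        return len(self._table)


def load_embedding_provider(path: str | Path) -> EmbeddingProvider:
    """Load an embedding table (CSV/TSV: first column key, rest numeric).

    The vector width is taken from the file; ragged rows raise a format
    error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise ValueError(f"{path.name}: need a key column plus numeric columns")
    keys = frame.iloc[:, 0].astype(str)
    values = frame.iloc[:, 1:]
    if values.isna().any().any():
        raise ValueError(f"{path.name}: ragged or missing vector entries")
    try:
        mat = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: non-numeric vector entries") from exc
    table = {k: mat[i] for i, k in enumerate(keys)}
    return EmbeddingProvider(table, dimension=mat.shape[1])


def compute_descriptor_matrix(
    dataset: ClassifiedDataset,
    provider_tag: str,
    embedding_provider: EmbeddingProvider | None = None,
    radius: int = 2,
    n_bits: int = 2048,
) -> DescriptorMatrix:
    """Featurize a curated data set under a named provider.

    Rows follow dataset member order. Compounds absent from an embedding
    table are dropped with a logged reason; callers narrow the dataset
    view with :func:`narrow_dataset` so labels stay aligned. Providers
    must return complete vectors — there is no silent imputation.
    """
    if provider_tag not in PROVIDER_TAGS:
        raise ValueError(
            f"unknown provider {provider_tag!r}; expected one of {PROVIDER_TAGS}"
        )
    records = [rec for rec, _ in dataset.members]
    dropped: list[tuple[str, str]] = []

    if provider_tag == "embedding":
        if embedding_provider is None:
            raise ValueError("embedding provider required for provider_tag='embedding'")
        vectors, keys = [], []
        for rec in records:
            vec = embedding_provider.get(rec.compound_key)
            if vec is None:
                dropped.append((rec.compound_key, "missing from embedding table"))
                logger.info("embedding miss for %s", rec.compound_key)
                continue
            vectors.append(vec)
            keys.append(rec.compound_key)
        dim = embedding_provider.dimension
        matrix = np.vstack(vectors) if vectors else np.empty((0, dim))
        names = [f"emb_{i}" for i in range(dim)]
        return DescriptorMatrix(provider_tag, matrix, names, keys, dropped)

    if provider_tag == "estate_like":
        rows = [compute_estate_vector(rec) for rec in records]
        width = len(rows[0]) if rows else 79
        matrix = np.vstack(rows) if rows else np.empty((0, width))
        names = [f"estate_{i}" for i in range(width)]
    else:  # fingerprint_bits
        rows = [
            compute_fingerprint(rec, radius=radius, n_bits=n_bits).to_array()
            for rec in records
        ]
        matrix = np.vstack(rows).astype(float) if rows else np.empty((0, n_bits))
        names = [f"bit_{i}" for i in range(n_bits)]

    keys = [rec.compound_key for rec in records]
    return DescriptorMatrix(provider_tag, matrix, names, keys, dropped)


def narrow_dataset(
    dataset: ClassifiedDataset, matrix: DescriptorMatrix
) -> ClassifiedDataset:
    """Restrict a data set to the compounds the matrix actually covers."""
    kept = set(matrix.compound_keys)
    idx = [i for i, (rec, _) in enumerate(dataset.members) if rec.compound_key in kept]
    return dataset.subset(idx)


def fingerprints_for(
    dataset: ClassifiedDataset, radius: int = 2, n_bits: int = 2048
) -> list[Fingerprint]:
    return [
        compute_fingerprint(rec, radius=radius, n_bits=n_bits)
        for rec, _ in dataset.members
    ]


def physchem_table(dataset: ClassifiedDataset) -> pd.DataFrame:
    """Physicochemical profile of every member, indexed by compound key."""
    rows = {
        rec.compound_key: compute_physchem(rec).__dict__ for rec, _ in dataset.members
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(PHYSCHEM_PROPERTIES)]
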