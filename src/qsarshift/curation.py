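"""Structure standardization and per-target binary data-set curation.

Standardization removes stereochemistry, strips salts to the largest
organic fragment, neutralizes charges and discards non-organic inputs,
so that the stereo-free InChI of the result is a stable identity key.

Classification binarizes IC50/Ki potencies at a micromolar threshold
(default 10 uM, inclusive on the active side). Replicate measurements of
the same compound are reconciled asymmetrically by data source:

* public-like source: replicates on both sides of the threshold are
  treated as irreconcilable noise and the compound is removed;
* proprietary-like source: one active replicate is enough to call the
  compound active, reflecting the tighter data management assumed for an
  in-house database and a preference for false positives over missed
  liabilities in off-target profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .config import RunConfig, logger
from .io import ActivityTableRow

RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INACTIVE = "inactive"

_uncharger = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class StandardizedStructure:
    canonical_smiles: str
    inchi: str
    inchikey: str


@dataclass(frozen=True)
class StructureRejection:
    structure: str
    reason: str  # "parse" | "nonorganic" | "empty"


@dataclass(frozen=True)
class Measurement:
    measurement_type: str
    value_um: float
    relation: str = "="
    assay_type: str | None = None
    cell_name: str | None = None
    assay_format: str | None = None


@dataclass(frozen=True)
class CompoundRecord:
    """A standardized compound with its pooled measurements for one target."""

    compound_key: str
    canonical_smiles: str
    inchi: str
    inchikey: str
    domain: str
    target_id: str
    measurements: tuple[Measurement, ...]


@dataclass
class ClassifiedDataset:
    """Curated per-target, per-domain set of labelled compounds."""

    target_id: str
    domain: str
    members: list[tuple[CompoundRecord, str]]
    curation_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.members]

    @property
    def inchis(self) -> set[str]:
        return {rec.inchi for rec, _ in self.members}

    def n_active(self) -> int:
        return sum(1 for _, lbl in self.members if lbl == ACTIVE)

    def minority_fraction(self) -> float:
        if not self.members:
            return 0.0
        na = self.n_active()
        return min(na, len(self.members) - na) / len(self.members)

    def subset(self, indices: Sequence[int]) -> "ClassifiedDataset":
        """A view-like copy restricted to the given member positions."""
        return ClassifiedDataset(
            target_id=self.target_id,
            domain=self.domain,
            members=[self.members[i] for i in indices],
            curation_log=list(self.curation_log),
        )


@dataclass(frozen=True)
class DatasetRejection:
    """A per-target data set that failed an eligibility criterion."""

    target_id: str
    domain: str
    reason: str
    n_compounds: int
    n_active: int


from functools import lru_cache


@lru_cache(maxsize=262144)
def standardize_compound(structure: str) -> StandardizedStructure | StructureRejection:
    """Standardize a SMILES (or SDF-derived SMILES) string.

    Largest organic fragment kept, charges neutralized where attainable,
    stereochemistry removed; the InChI/InChIKey are computed from the
    standardized structure. Inputs with no carbon atom are rejected as
    non-organic; unparsable inputs are rejected with reason ``parse``.
    Pure in its argument, so results are memoized.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        return StructureRejection(structure, "parse")
    if mol.GetNumAtoms() == 0:
        return StructureRejection(structure, "empty")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.FragmentParent(mol)  # strips salts/solvents
        mol = _uncharger.uncharge(mol)
    except Exception:  # rare sanitization corner cases
        return StructureRejection(structure, "parse")
    if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
        return StructureRejection(structure, "nonorganic")
    Chem.RemoveStereochemistry(mol)
    smiles = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        return StructureRejection(structure, "parse")
    return StandardizedStructure(
        canonical_smiles=smiles,
        inchi=inchi,
        inchikey=Chem.InchiToInchiKey(inchi),
    )


@dataclass(frozen=True)
class ClassRemoval:
    reason: str  # "conflict" | "no usable measurement"


def _measurement_label(m: Measurement, threshold_um: float) -> str | None:
    """Label one measurement, honouring the relation qualifier.

    ``>`` above the threshold is safely inactive, ``<`` at or below it is
    safely active; any other qualified measurement is unclassifiable and
    skipped (the caller logs it).
    """
    if m.relation in ("=", "unspecified"):
        return ACTIVE if m.value_um <= threshold_um else INACTIVE
    if m.relation == ">":
        return INACTIVE if m.value_um > threshold_um else None
    if m.relation == "<":
        return ACTIVE if m.value_um <= threshold_um else None
    return None


def assign_class(
    measurements: Iterable[Measurement],
    domain: str,
    threshold_um: float = 10.0,
) -> str | ClassRemoval:
    """Reconcile replicate measurements into one binary label.

    Active means potency <= ``threshold_um`` (inclusive: an exact-threshold
    value is active, so unit-conversion rounding cannot flip labels).
    Conflicting replicates remove the compound in the public-like domain
    but yield ``active`` in the proprietary-like domain.
    """
    labels = {
        lbl
        for m in measurements
        if (lbl := _measurement_label(m, threshold_um)) is not None
    }
    if not labels:
        return ClassRemoval("no usable measurement")
    if len(labels) == 1:
        return next(iter(labels))
    if domain == "proprietary_like":
        return ACTIVE
    return ClassRemoval("conflict")


def build_target_dataset(
    rows: Sequence[ActivityTableRow],
    target_id: str,
    domain: str,
    config: RunConfig | None = None,
) -> ClassifiedDataset | DatasetRejection:
    """Curate one target/domain slice of an activity table.

    Pipeline: standardize each structure, group measurements by the
    stereo-free InChI, reconcile replicate labels, then check the
    eligibility rules (minimum size, minimum minority-class fraction) on
    the final set. Every removal is recorded in the curation log; an
    ineligible set comes back as a :class:`DatasetRejection` carrying the
    observed counts.
    """
    config = config or RunConfig()
    rows = [r for r in rows if r.target_id == target_id and r.domain == domain]

    log: list[tuple[str, str, str]] = []
    # InChI -> (structure, representative key, measurements)
    groups: dict[str, tuple[StandardizedStructure, str, list[Measurement]]] = {}
    structure_cache: dict[str, StandardizedStructure | StructureRejection] = {}

    for row in rows:
        std = structure_cache.get(row.structure)
        if std is None:
            std = standardize_compound(row.structure)
            structure_cache[row.structure] = std
        if isinstance(std, StructureRejection):
            log.append((row.compound_key, "rejected", std.reason))
            continue
        meas = Measurement(
            measurement_type=row.measurement_type,
            value_um=row.value_um,
            relation=row.relation,
            assay_type=row.assay_type,
            cell_name=row.cell_name,
            assay_format=row.assay_format,
        )
        if std.inchi in groups:
            _, first_key, mlist = groups[std.inchi]
            if row.compound_key != first_key:
                log.append((row.compound_key, "merged", f"duplicate of {first_key}"))
            mlist.append(meas)
        else:
            groups[std.inchi] = (std, row.compound_key, [meas])

    members: list[tuple[CompoundRecord, str]] = []
    # sort by InChI so the output is independent of input row order
    for inchi in sorted(groups):
        std, key, mlist = groups[inchi]
        outcome = assign_class(
            sorted(mlist, key=lambda m: (m.measurement_type, m.value_um)),
            domain,
            config.activity_threshold_um,
        )
        if isinstance(outcome, ClassRemoval):
            log.append((key, "removed", outcome.reason))
            continue
        members.append(
            (
                CompoundRecord(
                    compound_key=key,
                    canonical_smiles=std.canonical_smiles,
                    inchi=inchi,
                    inchikey=std.inchikey,
                    domain=domain,
                    target_id=target_id,
                    measurements=tuple(
                        sorted(mlist, key=lambda m: (m.measurement_type, m.value_um))
                    ),
                ),
                outcome,
            )
        )

    n = len(members)
    n_active = sum(1 for _, lbl in members if lbl == ACTIVE)
    if n < config.min_dataset_size:
        logger.info("%s/%s rejected: size %d < %d", target_id, domain, n,
                    config.min_dataset_size)
        return DatasetRejection(
            target_id, domain, f"size < {config.min_dataset_size}", n, n_active
        )
    minority = min(n_active, n - n_active) / n
    if minority < config.min_minority_fraction:
        logger.info("%s/%s rejected: minority %.3f < %.3f", target_id, domain,
                    minority, config.min_minority_fraction)
        return DatasetRejection(
            target_id,
            domain,
            f"minority < {config.min_minority_fraction:.0%}",
            n,
            n_active,
        )
    return ClassifiedDataset(
        target_id=target_id, domain=domain, members=members, curation_log=log
    )


def dataset_to_rows(ds: ClassifiedDataset) -> list[dict]:
    """Flatten a curated data set for CSV export."""
    return [
        {
            "compound_key": rec.compound_key,
            "smiles": rec.canonical_smiles,
            "inchikey": rec.inchikey,
            "label": lbl,
        }
        for rec, lbl in ds.members
    ]
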