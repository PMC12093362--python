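"""Mixed training-set compilation from a proprietary-like base set plus
public-like data, under three increasingly restrictive strategies.

* approach ``a``: add every curated public compound for the target;
* approach ``b``: additionally require the public compound's assay
  format (cell-based / cell-free) to match the base set's format;
* approach ``c``: additionally require a maximum Tanimoto similarity to
  the base set of at least the configured threshold (default 0.230).

Public sources rarely annotate the assay format explicitly, so it is
derived from the assay-type code (Binding/ADME/Toxicity are retained)
combined with the presence of a cell-line annotation: a retained entry
with a cell name is cell-based, without one cell-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .config import RunConfig, logger
from .curation import ClassifiedDataset, CompoundRecord, build_target_dataset
from .descriptors import compute_descriptor_matrix, fingerprints_for
from .io import ActivityTableRow
from .nested_cv import NestedCVResult, run_nested_cv
from .splitting import tanimoto_matrix

APPROACHES = ("a_target_only", "b_plus_assay_format", "c_plus_similarity")

#: Assay-type codes retained when deriving the assay format of public rows.
RETAINED_ASSAY_TYPES = ("A", "B", "T")


@dataclass(frozen=True)
class MixingSpec:
    approach: str
    assay_format: str  # the base set's format: cell_based | cell_free
    similarity_threshold: float = 0.230

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.assay_format not in ("cell_based", "cell_free"):
            raise ValueError(f"unknown assay format {self.assay_format!r}")


@dataclass
class MixedDataset:
    """A compiled training set with per-member origin tags."""

    dataset: ClassifiedDataset
    origin_of: dict[str, str]  # compound_key -> "base" | "added_public"
    compilation_log: list[tuple[str, str, str]] = field(default_factory=list)

    def n_added(self) -> int:
        return sum(1 for o in self.origin_of.values() if o == "added_public")

    def inchi_set(self) -> set[str]:
        return self.dataset.inchis


def derive_assay_format_public(
    rows: Sequence[ActivityTableRow],
) -> tuple[list[ActivityTableRow], list[tuple[str, str]]]:
    """Annotate public-like rows with a derived assay format.

    Rows whose assay type is not one of Binding (B), ADME (A) or
    Toxicity (T) are excluded (and logged); among the retained rows, a
    cell-line annotation marks the measurement as cell-based, its absence
    as cell-free. Rows already carrying an explicit format keep it.
    """
    out: list[ActivityTableRow] = []
    excluded: list[tuple[str, str]] = []
    for row in rows:
        if row.assay_format is not None:
            out.append(row)
            continue
        if row.assay_type not in RETAINED_ASSAY_TYPES:
            excluded.append(
                (row.compound_key, f"assay type {row.assay_type!r} not in A/B/T")
            )
            continue
        fmt = "cell_based" if row.cell_name else "cell_free"
        out.append(
            ActivityTableRow(
                compound_key=row.compound_key,
                structure=row.structure,
                measurement_type=row.measurement_type,
                value_um=row.value_um,
                relation=row.relation,
                target_id=row.target_id,
                domain=row.domain,
                assay_type=row.assay_type,
                cell_name=row.cell_name,
                assay_format=fmt,
            )
        )
    if excluded:
        logger.info("assay-format derivation excluded %d rows", len(excluded))
    return out, excluded


def _format_of(rec: CompoundRecord) -> str | None:
    formats = {m.assay_format for m in rec.measurements if m.assay_format}
    if len(formats) == 1:
        return formats.pop()
    return None  # unknown or mixed-format compound


def compile_mixed(
    base_set: ClassifiedDataset,
    public_set: ClassifiedDataset,
    spec: MixingSpec,
    config: RunConfig | None = None,
) -> MixedDataset:
    """Compile one mixed training set under the given approach.

    The base set is taken whole; public compounds are appended subject to
    the approach's filters. On an InChI collision the base compound wins
    and the public copy is dropped (logged). By construction the member
    sets nest: approach c's additions are a subset of b's, and b's of a's.
    """
    if len(base_set) == 0:
        raise ValueError("the base (proprietary-like) set must be non-empty")
    config = config or RunConfig()
    log: list[tuple[str, str, str]] = []
    base_inchis = base_set.inchis

    candidates: list[int] = []
    for i, (rec, _) in enumerate(public_set.members):
        if rec.inchi in base_inchis:
            log.append((rec.compound_key, "dropped", "duplicate of base compound"))
            continue
        candidates.append(i)

    if spec.approach in ("b_plus_assay_format", "c_plus_similarity"):
        kept = []
        for i in candidates:
            rec, _ = public_set.members[i]
            fmt = _format_of(rec)
            if fmt == spec.assay_format:
                kept.append(i)
            else:
                log.append(
                    (rec.compound_key, "filtered",
                     f"assay format {fmt or 'unknown'} != {spec.assay_format}")
                )
        candidates = kept

    if spec.approach == "c_plus_similarity" and candidates:
        base_fps = fingerprints_for(
            base_set, radius=config.fingerprint_radius, n_bits=config.fingerprint_bits
        )
        cand_view = public_set.subset(candidates)
        cand_fps = fingerprints_for(
            cand_view, radius=config.fingerprint_radius, n_bits=config.fingerprint_bits
        )
        max_sim = tanimoto_matrix(cand_fps, base_fps).max(axis=1)
        kept = []
        for j, i in enumerate(candidates):
            rec, _ = public_set.members[i]
            if max_sim[j] >= spec.similarity_threshold:
                kept.append(i)
                log.append(
                    (rec.compound_key, "kept",
                     f"max base similarity {max_sim[j]:.3f}")
                )
            else:
                log.append(
                    (rec.compound_key, "filtered",
                     f"max base similarity {max_sim[j]:.3f} < "
                     f"{spec.similarity_threshold}")
                )
        candidates = kept

    members = list(base_set.members) + [public_set.members[i] for i in candidates]
    origin = {rec.compound_key: "base" for rec, _ in base_set.members}
    for i in candidates:
        origin[public_set.members[i][0].compound_key] = "added_public"
    mixed = ClassifiedDataset(
        target_id=base_set.target_id,
        domain="mixed",
        members=members,
        curation_log=list(base_set.curation_log),
    )
    return MixedDataset(dataset=mixed, origin_of=origin, compilation_log=log)


def evaluate_mixing(
    base_set: ClassifiedDataset,
    public_set: ClassifiedDataset,
    assay_format: str,
    config: RunConfig | None = None,
    algorithm_tag: str = "xgb",
    provider_tag: str = "estate_like",
    grid: Sequence[dict[str, Any]] | None = None,
    approaches: Sequence[str] = APPROACHES,
    schemes: Sequence[str] = ("random", "cluster"),
) -> list[dict[str, Any]]:
    """Nested-CV comparison of the three compilation approaches.

    Returns long-format fold records (approach, scheme, fold, mcc, ...)
    suitable for violin-style summaries of fold-level spread.
    """
    config = config or RunConfig()
    records: list[dict[str, Any]] = []
    for approach in approaches:
        spec = MixingSpec(
            approach=approach,
            assay_format=assay_format,
            similarity_threshold=config.similarity_threshold,
        )
        mixed = compile_mixed(base_set, public_set, spec, config)
        matrix = compute_descriptor_matrix(mixed.dataset, provider_tag)
        fps = fingerprints_for(
            mixed.dataset,
            radius=config.fingerprint_radius,
            n_bits=config.fingerprint_bits,
        )
        for scheme in schemes:
            result: NestedCVResult = run_nested_cv(
                mixed.dataset,
                matrix,
                algorithm_tag,
                scheme,
                config=config,
                grid=grid,
                fps=fps,
            )
            for rec in result.outer_records:
                records.append(
                    {
                        "approach": approach,
                        "scheme": scheme,
                        "fold": rec.fold,
                        "mcc": rec.report.mcc,
                        "balanced_accuracy": rec.report.balanced_accuracy,
                        "n_members": len(mixed.dataset),
                        "n_added": mixed.n_added(),
                    }
                )
    return records


def curate_mixing_inputs(
    base_rows: Sequence[ActivityTableRow],
    public_rows: Sequence[ActivityTableRow],
    target_id: str,
    config: RunConfig | None = None,
) -> tuple[ClassifiedDataset, ClassifiedDataset, list[tuple[str, str]]]:
    """Curate both sources for one target, deriving public assay formats."""
    config = config or RunConfig()
    annotated, excluded = derive_assay_format_public(public_rows)
    base = build_target_dataset(base_rows, target_id, "proprietary_like", config)
    public = build_target_dataset(annotated, target_id, "public_like", config)
    for ds, name in ((base, "base"), (public, "public")):
        if not isinstance(ds, ClassifiedDataset):
            raise ValueError(f"{name} set failed curation eligibility: {ds.reason}")
    return base, public, excluded
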