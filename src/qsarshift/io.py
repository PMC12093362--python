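"""Activity-table input, report output, and structure-file readers.

The table dialect defaults to ChEMBL bulk-export column names
(``canonical_smiles``, ``standard_type``, ``standard_value``, ...); a
mapping passed by the caller overrides any of them, so exports from other
databases can be read without rewriting files.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .config import logger

MEASUREMENT_TYPES = ("IC50", "Ki")
DOMAINS = ("public_like", "proprietary_like")
RELATIONS = ("=", "<", ">", "unspecified")
ASSAY_FORMATS = ("cell_based", "cell_free")

#: Default column mapping, following ChEMBL bulk-export conventions.
DEFAULT_DIALECT: dict[str, str] = {
    "compound_key": "molecule_chembl_id",
    "structure": "canonical_smiles",
    "measurement_type": "standard_type",
    "value": "standard_value",
    "units": "standard_units",
    "relation": "standard_relation",
    "target_id": "target_chembl_id",
    "domain": "source_domain",
    "assay_type": "assay_type",
    "cell_name": "assay_cell_type",
    "assay_format": "assay_format",
}

_OPTIONAL_FIELDS = ("relation", "assay_type", "cell_name", "assay_format")

# unit string -> factor converting a value to micromolar
_UNIT_TO_UM = {
    "nM": 1e-3,
    "nm": 1e-3,
    "uM": 1.0,
    "um": 1.0,
    "µM": 1.0,
    "μM": 1.0,
}


@dataclass(frozen=True)
class ActivityTableRow:
    """One bioactivity measurement, with the value normalized to micromolar."""

    compound_key: str
    structure: str
    measurement_type: str
    value_um: float
    relation: str
    target_id: str
    domain: str
    assay_type: str | None = None
    cell_name: str | None = None
    assay_format: str | None = None

    def __post_init__(self) -> None:
        if self.value_um <= 0:
            raise ValueError("measurement value must be positive")
        if self.measurement_type not in MEASUREMENT_TYPES:
            raise ValueError(f"unsupported measurement type {self.measurement_type}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain tag {self.domain}")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation}")


@dataclass(frozen=True)
class RejectedRow:
    """A raw table row that could not be parsed, with the reason kept."""

    line: int
    compound_key: str
    reason: str


class ConfigurationError(ValueError):
    """A mapped column is missing or a dialect entry is invalid."""


class EmptyInputError(ValueError):
    """The activity table has a header but no data rows."""


def _normalize_relation(raw: str | None) -> str:
    if raw is None:
        return "unspecified"
    raw = str(raw).strip().strip("'\"")
    if raw in ("", "nan", "None"):
        return "unspecified"
    if raw in ("=", "<", ">"):
        return raw
    # <= / >= carry the same classifiability as the strict forms here
    if raw == "<=":
        return "<"
    if raw == ">=":
        return ">"
    return "unspecified"


def read_activity_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
) -> tuple[list[ActivityTableRow], list[RejectedRow]]:
    """Read a CSV/TSV activity table into typed rows.

    Rows with an unparsable structure, non-numeric or non-positive value,
    or unconvertible units are collected into the returned rejects list
    with a reason, never silently dropped.

    Raises
    ------
    ConfigurationError
        If a mapped, required column is absent from the header.
    EmptyInputError
        If the file contains no data rows.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        colmap.update(dialect)

    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.empty:
        raise EmptyInputError(f"{path} contains no data rows")

    required = [f for f in colmap if f not in _OPTIONAL_FIELDS]
    missing = [colmap[f] for f in required if colmap[f] not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"mapped columns missing from {path.name}: {missing}"
        )

    have = {f: colmap[f] in frame.columns for f in colmap}
    rows: list[ActivityTableRow] = []
    rejects: list[RejectedRow] = []

    for line, rec in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, rec))
        key = str(rec[colmap["compound_key"]]).strip()

        def _opt(field: str) -> str | None:
            if not have[field]:
                return None
            v = str(rec[colmap[field]]).strip()
            return v or None

        raw_value = str(rec[colmap["value"]]).strip()
        try:
            value = float(raw_value)
        except ValueError:
            rejects.append(RejectedRow(line, key, "non-numeric value"))
            continue
        if not math.isfinite(value) or value <= 0:
            rejects.append(RejectedRow(line, key, "non-positive value"))
            continue

        units = str(rec[colmap["units"]]).strip()
        if units not in _UNIT_TO_UM:
            rejects.append(RejectedRow(line, key, f"unconvertible units '{units}'"))
            continue

        mtype = str(rec[colmap["measurement_type"]]).strip()
        if mtype not in MEASUREMENT_TYPES:
            rejects.append(RejectedRow(line, key, f"unsupported type '{mtype}'"))
            continue

        domain = str(rec[colmap["domain"]]).strip()
        if domain not in DOMAINS:
            rejects.append(RejectedRow(line, key, f"unknown domain '{domain}'"))
            continue

        structure = str(rec[colmap["structure"]]).strip()
        if not structure:
            rejects.append(RejectedRow(line, key, "empty structure"))
            continue

        assay_format = _opt("assay_format")
        if assay_format is not None and assay_format not in ASSAY_FORMATS:
            rejects.append(
                RejectedRow(line, key, f"unknown assay format '{assay_format}'")
            )
            continue

        rows.append(
            ActivityTableRow(
                compound_key=key,
                structure=structure,
                measurement_type=mtype,
                value_um=value * _UNIT_TO_UM[units],
                relation=_normalize_relation(_opt("relation")),
                target_id=str(rec[colmap["target_id"]]).strip(),
                domain=domain,
                assay_type=_opt("assay_type"),
                cell_name=_opt("cell_name"),
                assay_format=assay_format,
            )
        )

    if rejects:
        logger.info("read_activity_table: %d rows, %d rejects", len(rows), len(rejects))
    return rows, rejects


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file (one molecule per line, optional name column)."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            name = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            out.append((parts[0], name))
    return out


def read_sdf_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a V2000 SDF into (SMILES, name) pairs via RDKit."""
    out: list[tuple[str, str]] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        out.append((Chem.MolToSmiles(mol), name or f"mol{i}"))
    return out


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_report(obj: Any, path: str | Path, format: str = "json") -> None:
    """Serialize a pipeline product (dataclass, dict, or row list) to disk.

    JSON holds arbitrary nesting; CSV expects a list of flat mappings or
    dataclasses (one row each). An empty row list produces a valid empty
    file rather than an error.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_jsonable(obj), fh, indent=2, sort_keys=False)
            fh.write("\n")
    elif format == "csv":
        rows = obj if isinstance(obj, Sequence) else [obj]
        rows = [_to_jsonable(r) for r in rows]
        if not all(isinstance(r, dict) for r in rows):
            raise TypeError("CSV reports require flat row mappings")
        fieldnames: list[str] = []
        for r in rows:
            for k in r:
                if k not in fieldnames:
                    fieldnames.append(k)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            writer.writerows(rows)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> Any:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "csv":
        with open(path, newline="") as fh:
            return list(csv.DictReader(fh))
    raise ValueError(f"unknown report format {format!r}")


def write_rows_csv(rows: Iterable[Any], path: str | Path) -> None:
    """Convenience: write an iterable of dataclasses/dicts as CSV rows."""
    write_report(list(rows), path, format="csv")
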