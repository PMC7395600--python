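"""Reading and writing checklists and the Darwin-Core-style mapping file.

One CSV file holds the whole mapping (switchboard + base lists + program
lists), distinguished by the ``datasetName`` column, mirroring Darwin Core
Taxon term names bit-exactly:

``taxonID, parentNameUsageID, scientificName, taxonRank, datasetName,
conceptNote``

``conceptNote`` is a non-standard free-text column; leading
semicolon-separated tokens (``subsumed``, ``assess``) are machine-readable
link/curation markers, the remainder is curator prose.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .core import (
    Checklist,
    FormatError,
    IntegrityError,
    MappingFile,
    Role,
    SWITCHBOARD_SOURCE,
    TaxonRecord,
)
from .names import NameParseError, parse_scientific_name

__all__ = [
    "MAPPING_COLUMNS",
    "read_mapping_file",
    "write_mapping_file",
    "read_checklist",
]

MAPPING_COLUMNS = [
    "taxonID",
    "parentNameUsageID",
    "scientificName",
    "taxonRank",
    "datasetName",
    "conceptNote",
]


def _parse_row_name(raw: str, row_no: int, genus_context: str | None):
    try:
        return parse_scientific_name(raw, genus_context=genus_context)
    except NameParseError as exc:
        raise NameParseError("row %d: %s" % (row_no, exc)) from exc


def read_mapping_file(path: str | Path) -> MappingFile:
    """Load and structurally validate a mapping file.

    Checklist roles are derived from the parent chains: ``switchboard``
    rows have no parent, sources whose parents are switchboard rows are
    base lists, and sources whose parents are base rows are programs (the
    single base a program's rows point into is its declared authority).
    Row order is preserved within each source.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns and c != "conceptNote"]
    if missing:
        raise FormatError("mapping file %s missing columns: %s" % (path, missing))
    if "conceptNote" not in df.columns:
        df["conceptNote"] = ""

    records_by_source: dict[str, list[TaxonRecord]] = {}
    genus_context: dict[str, str] = {}
    ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        source = row.datasetName.strip()
        if not source:
            raise FormatError("row %d: empty datasetName" % i)
        name = _parse_row_name(
            row.scientificName, i, genus_context.get(source)
        )
        genus_context[source] = name.genus
        declared_rank = row.taxonRank.strip().lower()
        if declared_rank and declared_rank != name.rank.value:
            raise FormatError(
                "row %d: taxonRank %r inconsistent with parsed rank %r"
                % (i, row.taxonRank, name.rank.value)
            )
        tid = row.taxonID.strip()
        if not tid:
            raise FormatError("row %d: empty taxonID" % i)
        if tid in ids:
            raise IntegrityError("row %d: duplicate taxonID %r" % (i, tid))
        ids.add(tid)
        parent = row.parentNameUsageID.strip() or None
        records_by_source.setdefault(source, []).append(
            TaxonRecord(
                taxon_id=tid,
                parent_id=parent,
                name=name,
                source=source,
                note=row.conceptNote.strip(),
            )
        )

    checklists = _assemble_checklists(records_by_source)
    mapping = MappingFile(checklists)
    if not any(True for _ in mapping.records()):
        warnings.warn("mapping file %s contains a header but no records" % path)
        return mapping

    from .switchboard import validate_mapping  # late import: no cycle

    violations = validate_mapping(mapping)
    if violations:
        raise IntegrityError(
            "mapping file %s failed validation: %s"
            % (path, "; ".join(str(v) for v in violations[:5]))
        )
    return mapping


def _assemble_checklists(
    records_by_source: dict[str, list[TaxonRecord]]
) -> list[Checklist]:
    id_to_source = {
        rec.taxon_id: src
        for src, recs in records_by_source.items()
        for rec in recs
    }
    checklists: list[Checklist] = []
    switchboard_seen = False
    for source, recs in records_by_source.items():
        parent_sources = {
            id_to_source[r.parent_id]
            for r in recs
            if r.parent_id is not None and r.parent_id in id_to_source
        }
        if source == SWITCHBOARD_SOURCE or all(r.parent_id is None for r in recs):
            if source != SWITCHBOARD_SOURCE:
                raise FormatError(
                    "source %r has no parents but is not named %r"
                    % (source, SWITCHBOARD_SOURCE)
                )
            checklists.append(Checklist(source, Role.SWITCHBOARD, recs))
            switchboard_seen = True
        elif parent_sources <= {SWITCHBOARD_SOURCE}:
            checklists.append(Checklist(source, Role.BASE, recs))
        else:
            base_parents = sorted(parent_sources - {SWITCHBOARD_SOURCE})
            base_id = base_parents[0] if base_parents else None
            checklists.append(
                Checklist(source, Role.PROGRAM, recs, base_id=base_id)
            )
    if not switchboard_seen:
        checklists.insert(0, Checklist(SWITCHBOARD_SOURCE, Role.SWITCHBOARD, []))
    return checklists


def write_mapping_file(mapping: MappingFile, path: str | Path) -> Path:
    """Serialize a mapping file; ``read(write(m))`` is record-identical.

    Refuses to write a mapping that fails validation.
    """
    from .switchboard import validate_mapping

    violations = validate_mapping(mapping)
    if violations:
        raise IntegrityError(
            "refusing to write invalid mapping: %s"
            % "; ".join(str(v) for v in violations[:5])
        )
    path = Path(path)
    role_order = {Role.SWITCHBOARD: 0, Role.BASE: 1, Role.PROGRAM: 2}
    rows = []
    for cl in sorted(mapping.checklists.values(), key=lambda c: role_order[c.role]):
        for rec in cl.records:
            rows.append(
                {
                    "taxonID": rec.taxon_id,
                    "parentNameUsageID": rec.parent_id or "",
                    "scientificName": rec.name.canonical,
                    "taxonRank": rec.name.rank.value,
                    "datasetName": rec.source,
                    "conceptNote": rec.note,
                }
            )
    pd.DataFrame(rows, columns=MAPPING_COLUMNS).to_csv(path, index=False)
    return path


def read_checklist(
    path: str | Path,
    source_id: str,
    role: Role = Role.PROGRAM,
    base_id: str | None = None,
) -> Checklist:
    """Read a plain species checklist CSV (``scientificName[, taxonRank]``).

    Records get fresh sequential taxon ids and no parent links; linking to
    a base list is a later curation step. Duplicate names within a program
    list are rejected — program checklists are single-entry per taxon.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "scientificName" not in df.columns:
        raise FormatError("checklist %s lacks a scientificName column" % path)
    records: list[TaxonRecord] = []
    seen: set[str] = set()
    genus_context: str | None = None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        name = _parse_row_name(row.scientificName, i, genus_context)
        genus_context = name.genus
        if name.key in seen:
            raise IntegrityError(
                "row %d: duplicate name %r in program checklist %s"
                % (i, name.canonical, source_id)
            )
        seen.add(name.key)
        records.append(
            TaxonRecord(
                taxon_id="T%04d" % i,
                parent_id=None,
                name=name,
                source=source_id,
            )
        )
    return Checklist(source_id, role, records, base_id=base_id)
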