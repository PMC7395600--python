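"""Core domain types: taxon records, checklists and the mapping file.

The mapping file is a single Darwin-Core-Taxon-style table holding three
layers of checklist, tied together by parent/child identifier chains:

* ``switchboard`` — one master list of fine-grained taxon *concepts*
  (no parents);
* ``base`` lists — authoritative treatments (e.g. NABA, Opler & Warren,
  Pelham). Each base record ("holder") has a switchboard parent. A base
  list may repeat a name string across several holders when a single
  authoritative name subsumes several concepts — this duplication is what
  preserves the granularity of programs that split more finely than their
  authority;
* ``program`` lists — each monitoring program's working checklist. Each
  program record points at a holder in the program's declared base. A
  program name that covers several concepts appears on several rows, one
  per holder link.

A program→holder link is either *monitored* (the program collects data for
that concept: the concept occurs in the program's range) or *subsumed*
(the program's nomenclature circumscribes the concept, but no local data
exist). Subsumed rows carry the ``subsumed`` token in their concept note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

from .names import Rank, ScientificName

__all__ = [
    "Role",
    "SWITCHBOARD_SOURCE",
    "SUBSUMED_TOKEN",
    "ASSESS_TOKEN",
    "TaxonRecord",
    "Checklist",
    "MappingFile",
    "Violation",
    "MappingError",
    "FormatError",
    "IntegrityError",
    "MappingLookupError",
    "CurationError",
    "ClassificationError",
]

SWITCHBOARD_SOURCE = "switchboard"

#: Concept-note token marking a nomenclatural-only program→holder link.
SUBSUMED_TOKEN = "subsumed"
#: Concept-note token marking a record whose concept interpretation is
#: contested across authorities; translations touching it are flagged for
#: user assessment.
ASSESS_TOKEN = "assess"


class MappingError(Exception):
    """Base class for mapping-file problems."""


class FormatError(MappingError):
    """A file does not have the expected columns or shape."""


class IntegrityError(MappingError):
    """Structural invariants of a checklist or mapping are violated."""


class MappingLookupError(MappingError, KeyError):
    """An unknown source, name or complex was requested."""


class CurationError(MappingError):
    """A curation table entry is inconsistent or unusable."""


class ClassificationError(MappingError):
    """Donor concept structure cannot be classified (curation bug)."""


class Role(str, Enum):
    PROGRAM = "program"
    BASE = "base"
    SWITCHBOARD = "switchboard"


@dataclass(frozen=True)
class TaxonRecord:
    """One Darwin-Core-style row of the mapping file."""

    taxon_id: str
    parent_id: str | None
    name: ScientificName
    source: str
    note: str = ""

    @property
    def rank(self) -> Rank:
        return self.name.rank

    @property
    def subsumed(self) -> bool:
        return _has_token(self.note, SUBSUMED_TOKEN)

    @property
    def assess(self) -> bool:
        return _has_token(self.note, ASSESS_TOKEN)

    def with_note_token(self, token: str) -> "TaxonRecord":
        if _has_token(self.note, token):
            return self
        note = "%s; %s" % (token, self.note) if self.note else token
        return replace(self, note=note)


def _has_token(note: str, token: str) -> bool:
    head = [part.strip() for part in note.split(";")]
    return token in head


@dataclass
class Checklist:
    """An ordered list of records from one source."""

    source_id: str
    role: Role
    records: list[TaxonRecord] = field(default_factory=list)
    base_id: str | None = None  # programs only: declared base authority

    def __len__(self) -> int:
        return len(self.records)

    def names(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.name.canonical, None)
        return list(seen)

    def records_for(self, name_key: str) -> list[TaxonRecord]:
        return [r for r in self.records if r.name.key == name_key]


@dataclass(frozen=True)
class Violation:
    """One structural problem found by validation."""

    kind: str  # duplicate_id | dangling_parent | cycle | cross_role | orphan_root
    message: str
    taxon_id: str | None = None

    def __str__(self) -> str:  # pragma: no cover - display helper
        return "%s: %s" % (self.kind, self.message)


class MappingFile:
    """The whole three-layer mapping: switchboard, bases, programs."""

    def __init__(self, checklists: list[Checklist]):
        self.checklists: dict[str, Checklist] = {}
        for cl in checklists:
            if cl.source_id in self.checklists:
                raise IntegrityError("duplicate source %r" % cl.source_id)
            self.checklists[cl.source_id] = cl
        self._index: dict[str, TaxonRecord] = {}
        for rec in self.records():
            if rec.taxon_id in self._index:
                raise IntegrityError("duplicate taxon_id %r" % rec.taxon_id)
            self._index[rec.taxon_id] = rec

    # -- access ---------------------------------------------------------

    def records(self):
        for cl in self.checklists.values():
            yield from cl.records

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._index[taxon_id]
        except KeyError:
            raise MappingLookupError("unknown taxon_id %r" % taxon_id) from None

    def get(self, taxon_id: str) -> TaxonRecord | None:
        return self._index.get(taxon_id)

    def checklist(self, source_id: str) -> Checklist:
        try:
            return self.checklists[source_id]
        except KeyError:
            raise MappingLookupError("unknown source %r" % source_id) from None

    @property
    def switchboard(self) -> Checklist:
        for cl in self.checklists.values():
            if cl.role is Role.SWITCHBOARD:
                return cl
        raise IntegrityError("mapping has no switchboard checklist")

    def sources(self, role: Role) -> list[str]:
        return [s for s, cl in self.checklists.items() if cl.role is role]

    @property
    def programs(self) -> list[str]:
        return self.sources(Role.PROGRAM)

    @property
    def bases(self) -> list[str]:
        return self.sources(Role.BASE)

    # -- mutation helpers (used by curation / fixtures) -----------------

    def add_record(self, record: TaxonRecord) -> None:
        if record.taxon_id in self._index:
            raise IntegrityError("duplicate taxon_id %r" % record.taxon_id)
        self.checklist(record.source).records.append(record)
        self._index[record.taxon_id] = record

    def fresh_taxon_id(self) -> str:
        """Next free id in the "T"+zero-padded-integer scheme."""
        n = 0
        for tid in self._index:
            if tid.startswith("T") and tid[1:].isdigit():
                n = max(n, int(tid[1:]))
        return "T%04d" % (n + 1)
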