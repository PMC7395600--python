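"""The concept graph: switchboard nodes, base-list holders, program links.

The switchboard is a master list of taxon concepts at the finest
granularity any base list distinguishes. Base-list records ("holders")
each point at one switchboard concept; a base name that subsumes several
concepts is *duplicated* into one holder per concept so that programs
splitting more finely than their authority keep their granularity.

A program record reaches the switchboard in exactly two hops
(program -> base holder -> concept). ``concepts_of`` returns the
*monitored* closure — the concepts a program actually collects data for
under a name; ``circumscription_of`` additionally follows ``subsumed``
links, giving the full nomenclatural breadth of the program's usage
(e.g. a program applying its authority's wide species concept while only
two of its subtaxa fly locally).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .core import (
    Checklist,
    IntegrityError,
    MappingFile,
    MappingLookupError,
    Role,
    SWITCHBOARD_SOURCE,
    TaxonRecord,
    Violation,
)
from .names import ScientificName

__all__ = [
    "ConceptNode",
    "concept_nodes",
    "concepts_of",
    "circumscription_of",
    "add_holder",
    "validate_mapping",
]


@dataclass(frozen=True)
class ConceptNode:
    """One switchboard concept."""

    concept_id: str
    label: str
    complex_id: str | None = None

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.label


def _parse_kv_note(note: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in note.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _node_from_record(rec: TaxonRecord) -> ConceptNode:
    kv = _parse_kv_note(rec.note)
    label = kv.get("label", rec.name.canonical)
    return ConceptNode(rec.taxon_id, label, kv.get("complex"))


def concept_nodes(mapping: MappingFile, complex_id: str | None = None) -> list[ConceptNode]:
    """All switchboard concepts, optionally restricted to one complex."""
    nodes = [_node_from_record(r) for r in mapping.switchboard.records]
    if complex_id is not None:
        nodes = [n for n in nodes if n.complex_id == complex_id]
    return nodes


def _records_for(mapping: MappingFile, source_id: str, name: str) -> list[TaxonRecord]:
    cl = mapping.checklist(source_id)
    key = " ".join(name.split()).casefold()
    recs = cl.records_for(key)
    if not recs:
        raise MappingLookupError(
            "name %r not on the %s checklist" % (name, source_id)
        )
    return recs


def _ascend(mapping: MappingFile, rec: TaxonRecord) -> ConceptNode:
    cur = rec
    for _ in range(3):
        if cur.source == SWITCHBOARD_SOURCE:
            return _node_from_record(cur)
        if cur.parent_id is None:
            raise IntegrityError("record %s has no parent chain" % cur.taxon_id)
        cur = mapping[cur.parent_id]
    raise IntegrityError("parent chain from %s too deep" % rec.taxon_id)


def concepts_of(mapping: MappingFile, source_id: str, name: str) -> set[ConceptNode]:
    """Monitored upward closure of a name at a source.

    Union over every data-bearing record carrying the name (one program
    name may map to several holders), following parent ids up to the
    switchboard.
    """
    recs = _records_for(mapping, source_id, name)
    return {_ascend(mapping, r) for r in recs if not r.subsumed}


def circumscription_of(mapping: MappingFile, source_id: str, name: str) -> set[ConceptNode]:
    """Full concept breadth of a name at a source (monitored + subsumed)."""
    recs = _records_for(mapping, source_id, name)
    return {_ascend(mapping, r) for r in recs}


def add_holder(
    mapping: MappingFile,
    base_id: str,
    name: ScientificName,
    concept: ConceptNode,
    note: str = "",
) -> TaxonRecord:
    """Add a base-list holder for ``name`` under ``concept``.

    Duplicate name strings across holders are the mechanism that keeps
    concept granularity; a second holder for the identical
    (name, concept) pair is refused.
    """
    base = mapping.checklist(base_id)
    if base.role is not Role.BASE:
        raise MappingLookupError("%r is not a base list" % base_id)
    if concept.concept_id not in {r.taxon_id for r in mapping.switchboard.records}:
        raise MappingLookupError("unknown concept %r" % concept.concept_id)
    for rec in base.records_for(name.key):
        if rec.parent_id == concept.concept_id:
            raise IntegrityError(
                "holder (%s, %s) already present in %s"
                % (name.canonical, concept.label, base_id)
            )
    rec = TaxonRecord(
        taxon_id=mapping.fresh_taxon_id(),
        parent_id=concept.concept_id,
        name=name,
        source=base_id,
        note=note,
    )
    mapping.add_record(rec)
    return rec


def _checklist_violations(cl: Checklist) -> list[Violation]:
    out: list[Violation] = []
    seen: set[tuple[str, str | None]] = set()
    for rec in cl.records:
        pair = (rec.name.key, rec.parent_id)
        if pair in seen:
            out.append(
                Violation(
                    "duplicate_link",
                    "duplicate (name, parent) pair (%r, %r) in %s"
                    % (rec.name.canonical, rec.parent_id, cl.source_id),
                    rec.taxon_id,
                )
            )
        seen.add(pair)
    return out


def validate_mapping(mapping: MappingFile) -> list[Violation]:
    """Check every structural invariant; empty list means valid.

    Detected classes: dangling parents, parent cycles, cross-role parent
    rules (program -> its own base -> switchboard; switchboard roots have
    no parent), and duplicate (name, parent) links. Duplicate taxon ids
    cannot occur in a constructed :class:`MappingFile` — they are rejected
    at load time.
    """
    out: list[Violation] = []
    graph = nx.DiGraph()
    for rec in mapping.records():
        graph.add_node(rec.taxon_id)
        if rec.parent_id is not None:
            if mapping.get(rec.parent_id) is None:
                out.append(
                    Violation(
                        "dangling_parent",
                        "record %s (%s) points at missing parent %r"
                        % (rec.taxon_id, rec.name.canonical, rec.parent_id),
                        rec.taxon_id,
                    )
                )
            else:
                graph.add_edge(rec.taxon_id, rec.parent_id)
    try:
        cycle = nx.find_cycle(graph, orientation="original")
    except nx.NetworkXNoCycle:
        cycle = []
    if cycle:
        out.append(
            Violation(
                "cycle",
                "parent cycle through %s" % " -> ".join(e[0] for e in cycle),
                cycle[0][0],
            )
        )
        return out  # role checks below assume acyclic chains

    for cl in mapping.checklists.values():
        out.extend(_checklist_violations(cl))
        for rec in cl.records:
            parent = mapping.get(rec.parent_id) if rec.parent_id else None
            if cl.role is Role.SWITCHBOARD:
                if rec.parent_id is not None:
                    out.append(
                        Violation(
                            "cross_role",
                            "switchboard record %s must not have a parent" % rec.taxon_id,
                            rec.taxon_id,
                        )
                    )
            elif rec.parent_id is None:
                out.append(
                    Violation(
                        "cross_role",
                        "%s record %s lacks a parent" % (cl.role.value, rec.taxon_id),
                        rec.taxon_id,
                    )
                )
            elif parent is not None:
                parent_role = mapping.checklist(parent.source).role
                if cl.role is Role.BASE and parent_role is not Role.SWITCHBOARD:
                    out.append(
                        Violation(
                            "cross_role",
                            "base record %s must have a switchboard parent, got %s"
                            % (rec.taxon_id, parent.source),
                            rec.taxon_id,
                        )
                    )
                if cl.role is Role.PROGRAM and (
                    parent_role is not Role.BASE or parent.source != cl.base_id
                ):
                    out.append(
                        Violation(
                            "cross_role",
                            "program record %s must link into its declared base %r, got %r"
                            % (rec.taxon_id, cl.base_id, parent.source),
                            rec.taxon_id,
                        )
                    )
    return out
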