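"""Receiver→donor taxon translation through the switchboard.

Given a receiver program, one of its taxon names, and a donor program,
the translator walks the mapping graph: up from the receiver's records to
the switchboard concepts the name circumscribes, then down through the
donor's declared base list to the donor records that carry data for any
of those concepts. The result is classified:

PM
    perfect match — identical name string *and* identical concept
    circumscription;
CM
    compatible match — same data-concept, different nomenclature or a
    donor unit nested in the receiver's (wider) concept;
MM
    multiple match — the donor splits the receiver's unit into several
    names; all must be combined;
CM+
    the donor lumps the receiver's unit together with other taxa; donor
    data are combinable only with data from the receiver's sibling taxa;
ZERO
    no donor data fall within the receiver's concept ("species presumed
    absent").

Classification uses two concept sets per name: the *monitored* set (what
the program's data actually represent) and the *circumscription* (the
full breadth of the name as the program uses it). A donor name is a
candidate when its monitored set intersects the receiver's
circumscription. A sole non-lumping candidate is compatible only when it
shares monitored concepts with the receiver name or its own
circumscription lies inside the request — a donor whose concept reaches
beyond the receiver's request, with no shared data, is presumed absent
rather than silently equated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .core import (
    ClassificationError,
    MappingFile,
    MappingLookupError,
    Role,
    TaxonRecord,
)
from .switchboard import ConceptNode, _ascend, _records_for

__all__ = [
    "MatchType",
    "Flag",
    "MatchResult",
    "ReceiverView",
    "DonorCandidate",
    "ZERO_MESSAGE",
    "translate",
    "classify_match",
    "check_symmetry",
]

ZERO_MESSAGE = "There is no match in this list (species presumed absent)"


class MatchType(str, Enum):
    PM = "PM"
    CM = "CM"
    MM = "MM"
    CM_PLUS = "CM+"
    ZERO = "Zero"

    @property
    def kind(self) -> str:
        """Coarse kind used for symmetry checks; PM and CM differ only in
        nomenclature and count as the same kind."""
        return {
            MatchType.PM: "single",
            MatchType.CM: "single",
            MatchType.MM: "multiple",
            MatchType.CM_PLUS: "lump",
            MatchType.ZERO: "zero",
        }[self]


@dataclass(frozen=True)
class Flag:
    kind: str  # "asymmetry" | "complexity"
    message: str


@dataclass
class MatchResult:
    receiver: str
    receiver_name: str
    donor: str
    donor_names: list[str]
    match_type: MatchType
    flags: list[Flag] = field(default_factory=list)
    required_receiver_siblings: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def flagged(self) -> bool:
        return bool(self.flags)

    def to_dict(self) -> dict:
        return {
            "receiver": self.receiver,
            "receiver_name": self.receiver_name,
            "donor": self.donor,
            "match_type": self.match_type.value,
            "donor_names": list(self.donor_names),
            "flags": [{"kind": f.kind, "message": f.message} for f in self.flags],
            "required_receiver_siblings": list(self.required_receiver_siblings),
            "message": self.message,
        }


@dataclass(frozen=True)
class ReceiverView:
    """Concept view of the receiver's requested name."""

    name: str
    monitored: frozenset[str]
    circumscription: frozenset[str]
    #: monitored concepts of the receiver's *other* names, per name
    sibling_monitored: tuple[tuple[str, frozenset[str]], ...] = ()


@dataclass(frozen=True)
class DonorCandidate:
    """Concept view of one donor name whose data intersect the request."""

    name: str
    monitored: frozenset[str]
    circumscription: frozenset[str]


def classify_match(
    receiver: ReceiverView, candidates: list[DonorCandidate]
) -> tuple[MatchType, list[str], list[str]]:
    """Classify prepared donor candidates against a receiver view.

    Returns (match type, donor names, required receiver siblings).
    Candidates must each intersect the receiver circumscription.
    """
    R = receiver.circumscription
    if not R:
        raise ClassificationError("receiver concept set is empty")
    candidates = [c for c in candidates if c.monitored & R]
    if not candidates:
        return MatchType.ZERO, [], []

    lumps = [c for c in candidates if c.monitored - R]
    if lumps:
        if len(candidates) > 1:
            raise ClassificationError(
                "donor mixes lumping and non-lumping units for %r; "
                "curation must disambiguate" % receiver.name
            )
        lump = lumps[0]
        extra = lump.monitored - R
        sibs = sorted(
            name for name, mon in receiver.sibling_monitored if mon & extra
        )
        covered = set().union(
            *(mon for name, mon in receiver.sibling_monitored if mon & extra),
            set(),
        )
        if extra <= covered:
            return MatchType.CM_PLUS, [lump.name], sibs
        # the donor's pooled unit cannot be rebuilt from the receiver's
        # surveyed taxa: the donor has no usable data for this request
        return MatchType.ZERO, [], []

    if len(candidates) >= 2:
        return MatchType.MM, sorted(c.name for c in candidates), []

    sole = candidates[0]
    compatible = bool(sole.monitored & receiver.monitored) or (
        sole.circumscription <= R
    )
    if not compatible:
        return MatchType.ZERO, [], []
    if sole.name == receiver.name and sole.circumscription == R:
        return MatchType.PM, [sole.name], []
    return MatchType.CM, [sole.name], []


# ---------------------------------------------------------------------------
# graph traversal


def _concept_ids(mapping: MappingFile, recs: list[TaxonRecord], *, monitored_only: bool):
    out: set[str] = set()
    for rec in recs:
        if monitored_only and rec.subsumed:
            continue
        out.add(_ascend(mapping, rec).concept_id)
    return frozenset(out)


def _program_name_views(mapping: MappingFile, source_id: str):
    """Group a program's records by canonical name -> (records, views)."""
    cl = mapping.checklist(source_id)
    groups: dict[str, list[TaxonRecord]] = {}
    for rec in cl.records:
        groups.setdefault(rec.name.canonical, []).append(rec)
    return groups


def _receiver_view(mapping: MappingFile, receiver: str, name: str) -> tuple[ReceiverView, list[TaxonRecord]]:
    recs = _records_for(mapping, receiver, name)
    canonical = recs[0].name.canonical
    monitored = _concept_ids(mapping, recs, monitored_only=True)
    circ = _concept_ids(mapping, recs, monitored_only=False)
    sibs = []
    for other, other_recs in _program_name_views(mapping, receiver).items():
        if other == canonical:
            continue
        sibs.append(
            (other, _concept_ids(mapping, other_recs, monitored_only=True))
        )
    return (
        ReceiverView(canonical, monitored, circ, tuple(sorted(sibs))),
        recs,
    )


def _donor_candidates(
    mapping: MappingFile, donor: str, R: frozenset[str]
) -> tuple[list[DonorCandidate], list[TaxonRecord]]:
    """Descend from switchboard concepts R through the donor's base list."""
    donor_cl = mapping.checklist(donor)
    if donor_cl.role is not Role.PROGRAM:
        raise MappingLookupError("donor %r is not a program checklist" % donor)
    base_id = donor_cl.base_id
    holder_ids = {
        rec.taxon_id
        for rec in mapping.checklist(base_id).records
        if rec.parent_id in R
    }
    touched: dict[str, list[TaxonRecord]] = {}
    for rec in donor_cl.records:
        if rec.parent_id in holder_ids and not rec.subsumed:
            touched.setdefault(rec.name.canonical, []).append(rec)
    candidates = []
    cand_records: list[TaxonRecord] = []
    for cname in sorted(touched):
        all_recs = [
            r for r in donor_cl.records if r.name.canonical == cname
        ]
        candidates.append(
            DonorCandidate(
                cname,
                _concept_ids(mapping, all_recs, monitored_only=True),
                _concept_ids(mapping, all_recs, monitored_only=False),
            )
        )
        cand_records.extend(all_recs)
    return candidates, cand_records


def _complexes_of(mapping: MappingFile, concept_ids: frozenset[str]) -> set[str | None]:
    from .switchboard import _node_from_record

    out = set()
    for rec in mapping.switchboard.records:
        if rec.taxon_id in concept_ids:
            out.add(_node_from_record(rec).complex_id)
    return out


def _complexity_flags(
    mapping: MappingFile,
    result_type: MatchType,
    receiver_recs: list[TaxonRecord],
    candidate_recs: list[TaxonRecord],
    donor: str,
    R: frozenset[str],
    siblings: list[str],
) -> list[Flag]:
    flags: list[Flag] = []
    if result_type is MatchType.CM_PLUS:
        flags.append(
            Flag(
                "complexity",
                "donor data are only combinable when data from receiver "
                "taxa %s are included" % ", ".join(siblings),
            )
        )
    marked = [r for r in receiver_recs + candidate_recs if r.assess]
    if not marked and result_type is MatchType.ZERO:
        # a Zero against a donor whose treatment of this complex is itself
        # contested may be spurious; surface that
        complexes = _complexes_of(mapping, R)
        for rec in mapping.checklist(donor).records:
            if rec.assess and _complexes_of(
                mapping, _concept_ids(mapping, [rec], monitored_only=False)
            ) & complexes:
                marked.append(rec)
                break
    if marked:
        notes = []
        for rec in marked:
            text = _free_note_text(rec.note)
            if text and text not in notes:
                notes.append(text)
        msg = (
            "; ".join(notes)
            if notes
            else "concept interpretation contested; user must assess compatibility"
        )
        flags.append(Flag("complexity", msg))
    return flags


def _free_note_text(note: str) -> str:
    parts = [p.strip() for p in note.split(";")]
    keep = [
        p
        for p in parts
        if p and p not in ("subsumed", "assess") and "=" not in p
    ]
    return "; ".join(keep)


def _translate_inner(
    mapping: MappingFile, receiver: str, name: str, donor: str
) -> MatchResult:
    recv_cl = mapping.checklist(receiver)
    if recv_cl.role is not Role.PROGRAM:
        raise MappingLookupError("receiver %r is not a program checklist" % receiver)
    view, recv_recs = _receiver_view(mapping, receiver, name)
    candidates, cand_recs = _donor_candidates(mapping, donor, view.circumscription)
    mtype, donor_names, siblings = classify_match(view, candidates)
    flags = _complexity_flags(
        mapping, mtype, recv_recs, cand_recs, donor, view.circumscription, siblings
    )
    return MatchResult(
        receiver=receiver,
        receiver_name=view.name,
        donor=donor,
        donor_names=donor_names,
        match_type=mtype,
        flags=flags,
        required_receiver_siblings=siblings,
        message=ZERO_MESSAGE if mtype is MatchType.ZERO else "",
    )


def translate(
    mapping: MappingFile,
    receiver: str,
    name: str,
    donor: str,
    *,
    symmetry_check: bool = True,
) -> MatchResult:
    """Translate ``name`` from the receiver's checklist into the donor's.

    An unknown receiver name raises a lookup error; ZERO is reserved for
    the valid biological answer that the donor holds no data for the
    concept. With ``symmetry_check`` (default), the reverse request is run
    for each returned donor name and an asymmetry flag attached when the
    match kind differs.
    """
    result = _translate_inner(mapping, receiver, name, donor)
    if symmetry_check and receiver != donor:
        flag = _asymmetry_flag(mapping, result)
        if flag is not None:
            result.flags.append(flag)
    return result


def _asymmetry_flag(mapping: MappingFile, forward: MatchResult) -> Flag | None:
    for donor_name in forward.donor_names:
        reverse = _translate_inner(
            mapping, forward.donor, donor_name, forward.receiver
        )
        if reverse.match_type.kind != forward.match_type.kind:
            return Flag(
                "asymmetry",
                "reverse request (%s: %s -> %s) yields %s, not %s; "
                "the match is not symmetrical"
                % (
                    forward.donor,
                    donor_name,
                    forward.receiver,
                    reverse.match_type.value,
                    forward.match_type.value,
                ),
            )
    return None


def check_symmetry(
    mapping: MappingFile, receiver: str, name: str, donor: str
) -> Flag | None:
    """Run the reverse request for each donor name; return an asymmetry
    flag if any reverse match differs in kind, else None."""
    forward = _translate_inner(mapping, receiver, name, donor)
    return _asymmetry_flag(mapping, forward)
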