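"""Synthetic checklist networks with known ground truth.

The generator emulates the observed structure of a monitoring network: a
pool of fine-grained taxon concepts, a few authoritative base lists that
may *lump* same-genus concept pairs under one name (duplicated holders),
and program checklists derived from an assigned base with deviations
injected at per-name rates — genus swaps (G), spelling edits (L),
synonym replacements (S, with a matching curation entry, since synonymy
is curatorial knowledge), conglomerate pooling (C) and omissions (U).

Epithets come from a fixed syllable alphabet and are globally unique;
spelling edits keep the first two characters and stay within edit
distance 1, while synonym epithets differ in their first syllable — so
the two injection kinds can never be confused by the aligner. Lumpable
concept pairs are fixed globally before any list is derived, which keeps
any two lists' name-concept sets nested or disjoint (never partially
overlapping two different lumps).

Every injection is recorded in a :class:`GroundTruth` alongside the
expected receiver→donor match type for every (taxon, donor) pair,
derived by direct concept-set comparison — independently of the mapping
graph the translator walks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from ..core import Checklist, MappingFile, Role, SWITCHBOARD_SOURCE, TaxonRecord
from ..diff_engine import (
    CurationEntry,
    CurationTable,
    DiscrepancyCode,
    DiscrepancyType,
    SSubtype,
)
from ..names import parse_scientific_name

__all__ = ["SyntheticSpec", "GroundTruth", "synthesize", "oracle_match"]

_CONSONANTS = "bcdglmnprstvz"
_VOWELS = "aeiou"

_DEFAULT_RATES = {"G": 0.01, "S": 0.01, "L": 0.01, "C": 0.005, "U": 0.01}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic network.

    Default deviation rates reflect the magnitudes observed between real
    program lists and their authorities (totals of a few percent of
    names); ``lump_rate`` is the chance that a base list pools an
    eligible same-genus concept pair under one wide name.
    """

    seed: int
    n_concepts: int = 12
    n_base_lists: int = 2
    n_programs: int = 4
    rates: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    lump_rate: float = 0.1

    def validate(self) -> None:
        if self.n_programs < 2:
            raise ValueError("need at least two programs")
        if self.n_concepts < 1:
            raise ValueError("need at least one concept")
        if self.n_base_lists < 1:
            raise ValueError("need at least one base list")
        for code, p in self.rates.items():
            if code not in _DEFAULT_RATES:
                raise ValueError("unknown rate code %r" % code)
            if not 0.0 <= p <= 1.0:
                raise ValueError("rate %s=%r outside [0, 1]" % (code, p))
        if not 0.0 <= self.lump_rate <= 1.0:
            raise ValueError("lump_rate outside [0, 1]")
        if self.n_concepts < 2 and (
            self.rates.get("C", 0) > 0 or self.lump_rate > 0
        ):
            raise ValueError("lumping/conglomerates need at least two concepts")


@dataclass
class GroundTruth:
    """Everything the generator injected, for exact recovery checks."""

    #: program -> {code -> injected count}
    injected: dict[str, dict[str, int]]
    #: program -> {program name -> frozenset of concept epithets}
    program_concepts: dict[str, dict[str, frozenset[str]]]
    #: (receiver, receiver name, donor) -> expected match code
    expected_matches: dict[tuple[str, str, str], str]
    #: curation entries for the injected synonym (S) deviations
    curation: CurationTable
    #: program -> its base id
    base_of: dict[str, str]


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _fresh_word(rng: random.Random, n_syllables: int, taken: set[str]) -> str:
    while True:
        word = "".join(_syllable(rng) for _ in range(n_syllables))
        if word not in taken:
            taken.add(word)
            return word


def _fresh_synonym(rng: random.Random, original: str, taken: set[str]) -> str:
    """A fresh epithet whose first two characters differ from the
    original's, so it can never be read as a spelling variant."""
    while True:
        word = "".join(_syllable(rng) for _ in range(3))
        if word[:2] != original[:2] and word not in taken:
            taken.add(word)
            return word


def oracle_match(
    receiver_names: dict[str, frozenset[str]],
    receiver_name: str,
    donor_names: dict[str, frozenset[str]],
) -> str:
    """Expected match code by direct concept-set comparison.

    Independent of the mapping graph: operates on plain name→concept-set
    tables. Used both to build ground truth and as the brute-force
    cross-check for the translator's classification.
    """
    R = receiver_names[receiver_name]
    candidates = {y: s for y, s in donor_names.items() if s & R}
    if not candidates:
        return "Zero"
    lumps = {y: s for y, s in candidates.items() if s - R}
    if lumps:
        if len(candidates) > 1:
            raise ValueError("mixed lumping and non-lumping donor units")
        ((_, s),) = lumps.items()
        extra = s - R
        covered = set()
        for other, mon in receiver_names.items():
            if other != receiver_name:
                covered |= mon
        return "CM+" if extra <= covered else "Zero"
    if len(candidates) >= 2:
        return "MM"
    ((y, s),) = candidates.items()
    if y == receiver_name and s == R:
        return "PM"
    return "CM"


def synthesize(spec: SyntheticSpec) -> tuple[MappingFile, GroundTruth]:
    """Generate a mapping file and its ground truth; deterministic per seed."""
    spec.validate()
    rng = random.Random(spec.seed)
    taken: set[str] = set()

    n_genera = max(2, (spec.n_concepts + 3) // 4)
    genera = [
        _fresh_word(rng, 3, taken).capitalize() for _ in range(n_genera)
    ]
    epithets = [_fresh_word(rng, 3, taken) for _ in range(spec.n_concepts)]
    concepts = [
        (genera[i % n_genera], epithets[i]) for i in range(spec.n_concepts)
    ]

    # globally fixed lumpable pairs: consecutive concepts within a genus
    by_genus: dict[str, list[int]] = {}
    for idx, (genus, _) in enumerate(concepts):
        by_genus.setdefault(genus, []).append(idx)
    pair_of: dict[int, int] = {}
    for members in by_genus.values():
        for k in range(0, len(members) - 1, 2):
            pair_of[members[k]] = members[k + 1]
            pair_of[members[k + 1]] = members[k]

    next_id = [0]

    def tid() -> str:
        next_id[0] += 1
        return "T%05d" % next_id[0]

    switchboard = Checklist(SWITCHBOARD_SOURCE, Role.SWITCHBOARD)
    concept_ids: list[str] = []
    for genus, epithet in concepts:
        cid = tid()
        concept_ids.append(cid)
        switchboard.records.append(
            TaxonRecord(
                taxon_id=cid,
                parent_id=None,
                name=parse_scientific_name("%s %s" % (genus, epithet)),
                source=SWITCHBOARD_SOURCE,
                note="complex=%s; label=%s" % (genus, epithet),
            )
        )

    # base lists: every base covers all concepts; eligible pairs may be
    # lumped under the first member's name (duplicated holders)
    bases: list[Checklist] = []
    # base -> list of (name, [concept indices], [holder ids])
    base_inventory: dict[str, list[tuple[str, list[int], list[str]]]] = {}
    for b in range(spec.n_base_lists):
        base_id = "base%d" % (b + 1)
        cl = Checklist(base_id, Role.BASE)
        inventory: list[tuple[str, list[int], list[str]]] = []
        done: set[int] = set()
        for idx, (genus, epithet) in enumerate(concepts):
            if idx in done:
                continue
            partner = pair_of.get(idx)
            if (
                partner is not None
                and partner > idx
                and rng.random() < spec.lump_rate
            ):
                name = "%s %s" % (genus, epithet)
                hids = []
                for c in (idx, partner):
                    hid = tid()
                    hids.append(hid)
                    cl.records.append(
                        TaxonRecord(
                            taxon_id=hid,
                            parent_id=concept_ids[c],
                            name=parse_scientific_name(name),
                            source=base_id,
                        )
                    )
                inventory.append((name, [idx, partner], hids))
                done.update((idx, partner))
            else:
                name = "%s %s" % (genus, epithet)
                hid = tid()
                cl.records.append(
                    TaxonRecord(
                        taxon_id=hid,
                        parent_id=concept_ids[idx],
                        name=parse_scientific_name(name),
                        source=base_id,
                    )
                )
                inventory.append((name, [idx], [hid]))
                done.add(idx)
        bases.append(cl)
        base_inventory[base_id] = inventory

    # program lists with injected deviations
    programs: list[Checklist] = []
    injected: dict[str, dict[str, int]] = {}
    program_concepts: dict[str, dict[str, frozenset[str]]] = {}
    base_of: dict[str, str] = {}
    curation = CurationTable()
    order = ["U", "G", "L", "S", "C"]
    for p in range(spec.n_programs):
        program_id = "program%d" % (p + 1)
        base_id = "base%d" % (p % spec.n_base_lists + 1)
        base_of[program_id] = base_id
        cl = Checklist(program_id, Role.PROGRAM, base_id=base_id)
        counts = {c: 0 for c in order}
        name_sets: dict[str, frozenset[str]] = {}
        inventory = base_inventory[base_id]
        consumed: set[int] = set()
        for pos, (base_name, concept_idx, holder_ids) in enumerate(inventory):
            if pos in consumed:
                continue
            genus = concepts[concept_idx[0]][0]
            epithet_parts = [concepts[c][1] for c in concept_idx]
            draw = rng.random()
            cum = 0.0
            choice = None
            for code in order:
                cum += spec.rates.get(code, 0.0)
                if draw < cum:
                    choice = code
                    break

            prog_name = base_name
            all_idx = list(concept_idx)
            all_holders = list(holder_ids)
            if choice == "U":
                counts["U"] += 1
                continue
            if choice == "G":
                other = rng.choice([g for g in genera if g != genus])
                prog_name = "%s %s" % (other, epithet_parts[0])
                counts["G"] += 1
            elif choice == "L":
                edited = epithet_parts[0] + epithet_parts[0][-1]
                prog_name = "%s %s" % (genus, edited)
                counts["L"] += 1
            elif choice == "S":
                syn = _fresh_synonym(rng, epithet_parts[0], taken)
                prog_name = "%s %s" % (genus, syn)
                curation.add(
                    CurationEntry(
                        program_id,
                        prog_name,
                        base_id,
                        base_name,
                        DiscrepancyType(DiscrepancyCode.S, SSubtype.SYNONYM),
                        "injected synonym",
                    )
                )
                counts["S"] += 1
            elif choice == "C":
                partner = (
                    pair_of.get(concept_idx[0])
                    if len(concept_idx) == 1
                    else None
                )
                partner_pos = None
                if partner is not None and partner not in consumed:
                    for q in range(pos + 1, len(inventory)):
                        qname, qidx, qhold = inventory[q]
                        if qidx == [partner] and q not in consumed:
                            partner_pos = q
                            break
                if partner_pos is None:
                    pass  # no eligible partner; no injection
                else:
                    qname, qidx, qhold = inventory[partner_pos]
                    consumed.add(partner_pos)
                    prog_name = "%s %s/%s" % (
                        genus,
                        epithet_parts[0],
                        concepts[partner][1],
                    )
                    all_idx = concept_idx + qidx
                    all_holders = holder_ids + qhold
                    counts["C"] += 1

            name_sets[prog_name] = frozenset(
                concepts[c][1] for c in all_idx
            )
            for hid in all_holders:
                cl.records.append(
                    TaxonRecord(
                        taxon_id=tid(),
                        parent_id=hid,
                        name=parse_scientific_name(prog_name),
                        source=program_id,
                    )
                )
        programs.append(cl)
        injected[program_id] = counts
        program_concepts[program_id] = name_sets

    expected: dict[tuple[str, str, str], str] = {}
    for receiver, r_names in program_concepts.items():
        for donor, d_names in program_concepts.items():
            if donor == receiver:
                continue
            for name in r_names:
                expected[(receiver, name, donor)] = oracle_match(
                    r_names, name, d_names
                )

    mapping = MappingFile([switchboard] + bases + programs)
    truth = GroundTruth(
        injected=injected,
        program_concepts=program_concepts,
        expected_matches=expected,
        curation=curation,
        base_of=base_of,
    )
    return mapping, truth
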