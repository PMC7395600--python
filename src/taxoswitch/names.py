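"""Parsing, normalization and comparison of scientific-name strings.

Checklists of North American butterfly monitoring programs use four shapes
of name: plain binomials (``Hesperia comma``), trinomials where a program
records to subspecies (``Speyeria cybele leto``), bare genus or subfamily
headers, and *conglomerates* — a single entry deliberately pooling two
field-indistinguishable congeners, written with a slash
(``Colias eurytheme/philodice``). All of these round-trip through
:func:`parse_scientific_name` / :func:`canonical_string`.

Stored strings preserve the program's sanctioned spelling; matching for
lookup is case-insensitive and whitespace-normalized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import edlib

__all__ = [
    "Rank",
    "ScientificName",
    "NameParseError",
    "parse_scientific_name",
    "canonical_string",
    "epithet_distance",
]


class NameParseError(ValueError):
    """Raised when a name string cannot be interpreted."""


class Rank(str, Enum):
    SUBFAMILY = "subfamily"
    GENUS = "genus"
    SPECIES = "species"
    SUBSPECIES = "subspecies"
    CONGLOMERATE = "conglomerate"


_ABBREV_RE = re.compile(r"^([A-Z])\.$")
_EPITHET_RE = re.compile(r"^[a-z][a-z-]*$")
_GENUS_RE = re.compile(r"^[A-Z][a-z-]+$")


@dataclass(frozen=True)
class ScientificName:
    """A parsed scientific name.

    ``conglomerate_epithets`` is non-empty (length >= 2) exactly when
    ``rank`` is :attr:`Rank.CONGLOMERATE`; ``infraspecific`` is non-empty
    exactly when ``rank`` is :attr:`Rank.SUBSPECIES`.
    """

    raw: str
    genus: str
    epithet: str = ""
    infraspecific: str = ""
    conglomerate_epithets: tuple[str, ...] = field(default_factory=tuple)
    rank: Rank = Rank.SPECIES

    def __post_init__(self) -> None:
        if self.rank is Rank.CONGLOMERATE:
            if len(self.conglomerate_epithets) < 2:
                raise NameParseError(
                    "conglomerate names need at least two epithets: %r" % self.raw
                )
        elif self.conglomerate_epithets:
            raise NameParseError(
                "conglomerate_epithets only allowed at conglomerate rank: %r" % self.raw
            )

    @property
    def canonical(self) -> str:
        return canonical_string(self)

    @property
    def key(self) -> str:
        """Case-insensitive lookup key."""
        return self.canonical.casefold()

    def epithets(self) -> tuple[str, ...]:
        """All epithet-level components (for the distinct-epithet census)."""
        parts: list[str] = []
        if self.rank is Rank.CONGLOMERATE:
            parts.extend(self.conglomerate_epithets)
        elif self.epithet:
            parts.append(self.epithet)
        if self.infraspecific:
            parts.append(self.infraspecific)
        return tuple(parts)


def _normalize_token(tok: str, *, lower: bool) -> str:
    return tok.lower() if lower else tok


def parse_scientific_name(
    raw: str, *, genus_context: str | None = None
) -> ScientificName:
    """Parse a name string into its components.

    Parameters
    ----------
    raw
        The name as it appears on a checklist. Slash-separated epithets
        (``"Celastrina ladon/neglecta"``) yield a conglomerate; three
        space-separated tokens yield a subspecies.
    genus_context
        Expansion context for an abbreviated genus such as ``"C. ladon"``.
        Tables routinely abbreviate, but mapping files must be unambiguous,
        so a bare abbreviation without context is a parse error.
    """
    text = " ".join(raw.split())
    if not text:
        raise NameParseError("empty name string")
    tokens = text.split(" ")

    genus = tokens[0]
    m = _ABBREV_RE.match(genus)
    if m:
        if genus_context is None:
            raise NameParseError(
                "abbreviated genus %r without a genus context" % genus
            )
        if not genus_context or genus_context[0].upper() != m.group(1):
            raise NameParseError(
                "abbreviation %r does not match context genus %r"
                % (genus, genus_context)
            )
        genus = genus_context
    genus = genus[0].upper() + genus[1:].lower()
    if not _GENUS_RE.match(genus):
        raise NameParseError("malformed genus token %r in %r" % (tokens[0], raw))

    if len(tokens) == 1:
        rank = Rank.SUBFAMILY if genus.endswith("inae") else Rank.GENUS
        return ScientificName(raw=raw, genus=genus, rank=rank)
    if len(tokens) > 3:
        raise NameParseError("too many name tokens (%d) in %r" % (len(tokens), raw))

    epithet_tok = tokens[1].lower()
    if "/" in epithet_tok:
        if len(tokens) > 2:
            raise NameParseError(
                "conglomerate with trailing tokens not supported: %r" % raw
            )
        parts = tuple(p for p in epithet_tok.split("/") if p)
        if len(parts) < 2:
            raise NameParseError("malformed conglomerate %r" % raw)
        for p in parts:
            if not _EPITHET_RE.match(p):
                # an uppercase component would be a cross-genus conglomerate
                raise NameParseError(
                    "conglomerate components must be congeneric epithets: %r" % raw
                )
        return ScientificName(
            raw=raw,
            genus=genus,
            conglomerate_epithets=parts,
            rank=Rank.CONGLOMERATE,
        )

    if not _EPITHET_RE.match(epithet_tok):
        raise NameParseError("malformed epithet %r in %r" % (tokens[1], raw))
    if len(tokens) == 2:
        return ScientificName(raw=raw, genus=genus, epithet=epithet_tok)

    infra = tokens[2].lower()
    if "/" in infra or not _EPITHET_RE.match(infra):
        raise NameParseError("malformed infraspecific epithet %r in %r" % (tokens[2], raw))
    return ScientificName(
        raw=raw,
        genus=genus,
        epithet=epithet_tok,
        infraspecific=infra,
        rank=Rank.SUBSPECIES,
    )


def canonical_string(name: ScientificName) -> str:
    """Deterministic single-space form: ``Genus epithet[/e2...][ infraspecific]``.

    Idempotent under re-parse: ``parse(canonical(parse(s)))`` equals
    ``parse(s)`` for every valid ``s``.
    """
    if name.rank in (Rank.GENUS, Rank.SUBFAMILY):
        return name.genus
    if name.rank is Rank.CONGLOMERATE:
        return "%s %s" % (name.genus, "/".join(name.conglomerate_epithets))
    if name.rank is Rank.SUBSPECIES:
        return "%s %s %s" % (name.genus, name.epithet, name.infraspecific)
    return "%s %s" % (name.genus, name.epithet)


def epithet_distance(a: str, b: str) -> int:
    """Levenshtein distance between two lowercase epithets.

    Used to propose spelling-deviation (L) candidates, e.g.
    ``edwardsi`` vs ``edwardsii`` -> 1. Symmetric; zero iff equal.
    """
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])
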