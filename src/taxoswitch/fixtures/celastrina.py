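"""The *Celastrina ladon* complex fixture.

Ten North American butterfly monitoring programs monitor five members of
the azure complex (*ladon*, *neglecta*, *lucia*, *echo*, *humulus*; two
further members, *serotina* and *idella*, fly outside every program's
area) under three authoritative base treatments. NABA treats the whole
complex as subtaxa of one wide *C. ladon*; Opler & Warren and Pelham
treat the members as full species. Programs additionally deviate from
their declared authority — splitting *neglecta* out, pooling *ladon* and
*neglecta* into a conglomerate name, or applying a trinomial.

Every program→holder link here is curated: the monitored links encode
which concepts a program's data actually cover (the taxa flying in its
area), the subsumed links encode the extra breadth of the name as the
program uses it, and the ``assess`` markers encode which records'
interpretations the curators judged contested. The companion
:func:`expected_celastrina_matrix` is the hand-built integration matrix
for the complex, which doubles as the translator's regression surface.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..core import Checklist, MappingFile, Role, SWITCHBOARD_SOURCE, TaxonRecord
from ..matrix import Cell, IntegrationMatrix
from ..names import parse_scientific_name

__all__ = [
    "CELASTRINA_COMPLEX",
    "PROGRAM_ORDER",
    "PROGRAM_ABBREVIATIONS",
    "celastrina_fixture",
    "expected_celastrina_matrix",
    "bundled_mapping_path",
    "bundled_expected_matrix_path",
]

CELASTRINA_COMPLEX = "Celastrina-ladon-complex"

PROGRAM_ORDER = [
    "Illinois",
    "Iowa",
    "Michigan",
    "Ohio",
    "Tennessee",
    "Florida",
    "Cascades",
    "MPG",
    "Colorado",
    "Orange County",
]

PROGRAM_ABBREVIATIONS = {
    "Illinois": "IL",
    "Iowa": "IA",
    "Michigan": "MI",
    "Ohio": "OH",
    "Tennessee": "TN",
    "Florida": "FL",
    "Cascades": "CAS",
    "MPG": "MPG",
    "Colorado": "CO",
    "Orange County": "OC",
}

_CONCEPTS = [
    "ladon",
    "neglecta",
    "lucia",
    "echo",
    "humulus",
    "serotina",  # outside every program's monitoring area
    "idella",  # outside every program's monitoring area
]

_CONTESTED = "concept interpretation contested across authorities; user must assess compatibility"

# program -> (base, [(name, monitored, subsumed, assess, note), ...])
_PROGRAMS: dict[str, tuple[str, list]] = {
    "Illinois": (
        "NABA",
        [
            (
                "Celastrina ladon/neglecta",
                ["ladon", "neglecta"],
                ["lucia", "echo", "humulus"],
                True,
                "conglomerate of field-indistinguishable taxa under the authority's wide species concept",
            )
        ],
    ),
    "Iowa": (
        "NABA",
        [
            (
                "Celastrina ladon",
                ["ladon", "neglecta"],
                ["lucia", "echo", "humulus"],
                True,
                "one name collects both local subtaxa under the authority's wide species concept",
            )
        ],
    ),
    "Michigan": (
        "NABA",
        [
            (
                "Celastrina ladon/neglecta",
                ["ladon", "neglecta"],
                ["lucia", "echo", "humulus"],
                True,
                "conglomerate of field-indistinguishable taxa under the authority's wide species concept",
            )
        ],
    ),
    "Ohio": (
        "NABA",
        [
            (
                "Celastrina ladon",
                ["ladon"],
                ["lucia", "echo", "humulus"],
                True,
                "program splits neglecta out of the authority's wide species concept",
            ),
            (
                "Celastrina neglecta",
                ["neglecta"],
                [],
                True,
                "split from the authority's wide species concept",
            ),
        ],
    ),
    "Tennessee": (
        "NABA",
        [
            (
                "Celastrina ladon/neglecta",
                ["ladon", "neglecta"],
                ["lucia", "echo", "humulus"],
                True,
                "conglomerate of field-indistinguishable taxa under the authority's wide species concept",
            )
        ],
    ),
    "Florida": (
        "OW",
        [
            ("Celastrina ladon", ["ladon"], [], True, _CONTESTED),
            ("Celastrina neglecta", ["neglecta"], [], True, _CONTESTED),
        ],
    ),
    "Cascades": (
        "Pelham",
        [
            (
                "Celastrina lucia",
                ["lucia"],
                [],
                True,
                "lucia/echo segregates are difficult to distinguish near their range contact",
            ),
            (
                "Celastrina echo",
                ["echo"],
                [],
                True,
                "lucia/echo segregates are difficult to distinguish near their range contact",
            ),
        ],
    ),
    "MPG": (
        "Pelham",
        [
            (
                "Celastrina echo",
                ["echo"],
                [],
                False,
                "only one member of the complex occurs locally",
            )
        ],
    ),
    "Colorado": (
        "OW",
        [
            ("Celastrina ladon", ["ladon"], [], True, _CONTESTED),
            ("Celastrina humulus", ["humulus"], [], True, _CONTESTED),
        ],
    ),
    "Orange County": (
        "OW",
        [
            (
                "Celastrina ladon echo",
                ["echo"],
                ["ladon", "lucia"],
                False,
                "local population unambiguous; trinomial reflects a wide-ladon interpretation",
            )
        ],
    ),
}

# base -> [(holder name, concept), ...]; NABA's single wide name is
# duplicated into one holder per concept it subsumes
_BASES: dict[str, list[tuple[str, str]]] = {
    "NABA": [
        ("Celastrina ladon", "ladon"),
        ("Celastrina ladon", "neglecta"),
        ("Celastrina ladon", "lucia"),
        ("Celastrina ladon", "echo"),
        ("Celastrina ladon", "humulus"),
    ],
    "OW": [
        ("Celastrina ladon", "ladon"),
        ("Celastrina neglecta", "neglecta"),
        ("Celastrina lucia", "lucia"),
        ("Celastrina echo", "echo"),
        ("Celastrina humulus", "humulus"),
    ],
    "Pelham": [
        ("Celastrina lucia", "lucia"),
        ("Celastrina echo", "echo"),
    ],
}


def celastrina_fixture() -> MappingFile:
    """Build the curated mapping for the *C. ladon* complex in code."""
    next_id = [0]

    def tid() -> str:
        next_id[0] += 1
        return "T%04d" % next_id[0]

    concept_ids: dict[str, str] = {}
    switchboard = Checklist(SWITCHBOARD_SOURCE, Role.SWITCHBOARD)
    for epithet in _CONCEPTS:
        cid = tid()
        concept_ids[epithet] = cid
        switchboard.records.append(
            TaxonRecord(
                taxon_id=cid,
                parent_id=None,
                name=parse_scientific_name("Celastrina %s" % epithet),
                source=SWITCHBOARD_SOURCE,
                note="complex=%s; label=%s" % (CELASTRINA_COMPLEX, epithet),
            )
        )

    holder_ids: dict[tuple[str, str], str] = {}
    bases = []
    for base_name, holders in _BASES.items():
        cl = Checklist(base_name, Role.BASE)
        for name, concept in holders:
            hid = tid()
            holder_ids[(base_name, concept)] = hid
            cl.records.append(
                TaxonRecord(
                    taxon_id=hid,
                    parent_id=concept_ids[concept],
                    name=parse_scientific_name(name),
                    source=base_name,
                )
            )
        bases.append(cl)

    programs = []
    for program in PROGRAM_ORDER:
        base_name, entries = _PROGRAMS[program]
        cl = Checklist(program, Role.PROGRAM, base_id=base_name)
        for name, monitored, subsumed, assess, note in entries:
            for concept in monitored:
                tokens = ["assess"] if assess else []
                cl.records.append(
                    TaxonRecord(
                        taxon_id=tid(),
                        parent_id=holder_ids[(base_name, concept)],
                        name=parse_scientific_name(name),
                        source=program,
                        note="; ".join(tokens + [note]),
                    )
                )
            for concept in subsumed:
                tokens = ["subsumed"] + (["assess"] if assess else [])
                cl.records.append(
                    TaxonRecord(
                        taxon_id=tid(),
                        parent_id=holder_ids[(base_name, concept)],
                        name=parse_scientific_name(name),
                        source=program,
                        note="; ".join(tokens + [note]),
                    )
                )
        programs.append(cl)

    return MappingFile([switchboard] + bases + programs)


# Expected integration matrix for the complex (receiver taxa in rows,
# donor programs in columns, same program order as PROGRAM_ORDER).
_DONORS = PROGRAM_ORDER
_EXPECTED_ROWS: list[tuple[str, str, list[str]]] = [
    ("Illinois", "Celastrina ladon/neglecta",
     ["X", "CM", "PM", "MM", "PM", "MM", "MM", "CM", "MM", "CM"]),
    ("Iowa", "Celastrina ladon",
     ["CM", "X", "CM", "MM", "CM", "MM", "MM", "CM", "MM", "CM"]),
    ("Michigan", "Celastrina ladon/neglecta",
     ["PM", "CM", "X", "MM", "PM", "MM", "MM", "CM", "MM", "CM"]),
    ("Ohio", "Celastrina ladon",
     ["CM+", "CM+", "CM+", "X", "CM+", "CM", "MM", "CM", "MM", "CM"]),
    ("Ohio", "Celastrina neglecta",
     ["CM+", "CM+", "CM+", "X", "CM+", "PM", "Zero", "Zero", "Zero", "Zero"]),
    ("Tennessee", "Celastrina ladon/neglecta",
     ["PM", "CM", "PM", "MM", "X", "MM", "MM", "CM", "MM", "CM"]),
    ("Florida", "Celastrina ladon",
     ["CM+", "CM+", "CM+", "CM", "CM+", "X", "Zero", "Zero", "PM", "Zero"]),
    ("Florida", "Celastrina neglecta",
     ["CM+", "CM+", "CM+", "PM", "CM+", "X", "Zero", "Zero", "Zero", "Zero"]),
    ("Cascades", "Celastrina lucia",
     ["Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "X", "Zero", "Zero", "Zero"]),
    ("Cascades", "Celastrina echo",
     ["Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "X", "PM", "Zero", "CM"]),
    ("MPG", "Celastrina echo",
     ["Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "PM", "X", "Zero", "CM"]),
    ("Colorado", "Celastrina ladon",
     ["Zero", "Zero", "Zero", "CM", "Zero", "PM", "Zero", "Zero", "X", "Zero"]),
    ("Colorado", "Celastrina humulus",
     ["Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "Zero", "X", "Zero"]),
    ("Orange County", "Celastrina ladon echo",
     ["Zero", "Zero", "Zero", "Zero", "Zero", "CM", "MM", "CM", "CM", "X"]),
]

#: The only two requests in the complex that carry no warning flag:
#: Orange County and MPG monitor the same single unambiguous taxon.
_UNFLAGGED = {
    ("Orange County", "Celastrina ladon echo", "MPG"),
    ("MPG", "Celastrina echo", "Orange County"),
}


def expected_celastrina_matrix() -> IntegrationMatrix:
    """The curated integration matrix for the *C. ladon* complex."""
    rows = [(p, t) for p, t, _ in _EXPECTED_ROWS]
    cells: dict[tuple[str, str, str], Cell] = {}
    for program, taxon, codes in _EXPECTED_ROWS:
        for donor, code in zip(_DONORS, codes):
            if code == "X":
                cells[(program, taxon, donor)] = Cell("X")
            else:
                flagged = (program, taxon, donor) not in _UNFLAGGED
                cells[(program, taxon, donor)] = Cell(code, flagged)
    return IntegrationMatrix(CELASTRINA_COMPLEX, rows, list(_DONORS), cells)


def _data_path(name: str) -> Path:
    return Path(resources.files("taxoswitch").joinpath("data", name))


def bundled_mapping_path() -> Path:
    """Path to the committed CSV form of :func:`celastrina_fixture`."""
    return _data_path("celastrina_mapping.csv")


def bundled_expected_matrix_path() -> Path:
    """Path to the committed CSV form of the expected matrix."""
    return _data_path("celastrina_expected_matrix.csv")
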