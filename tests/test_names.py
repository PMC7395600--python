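"""Scientific-name parsing, canonical forms and epithet distances."""

import pytest
from hypothesis import given, strategies as st

from taxoswitch import (
    NameParseError,
    Rank,
    canonical_string,
    epithet_distance,
    parse_scientific_name,
)

EPITHET = st.text(alphabet="abcdefghilmnoprstuz", min_size=1, max_size=10)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle over all alignments."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


@pytest.mark.parametrize(
    "raw, genus, epithet, infra, conglom, rank",
    [
        ("Hesperia comma", "Hesperia", "comma", "", (), Rank.SPECIES),
        ("Speyeria cybele leto", "Speyeria", "cybele", "leto", (), Rank.SUBSPECIES),
        (
            "Celastrina ladon/neglecta",
            "Celastrina",
            "",
            "",
            ("ladon", "neglecta"),
            Rank.CONGLOMERATE,
        ),
        (
            "Colias eurytheme/philodice",
            "Colias",
            "",
            "",
            ("eurytheme", "philodice"),
            Rank.CONGLOMERATE,
        ),
        ("Atrytonopsis edwardsii", "Atrytonopsis", "edwardsii", "", (), Rank.SPECIES),
        ("Celastrina", "Celastrina", "", "", (), Rank.GENUS),
        ("Polyommatinae", "Polyommatinae", "", "", (), Rank.SUBFAMILY),
        ("  Celastrina   ladon ", "Celastrina", "ladon", "", (), Rank.SPECIES),
    ],
)
def test_parse_components(raw, genus, epithet, infra, conglom, rank):
    name = parse_scientific_name(raw)
    assert name.genus == genus
    assert name.epithet == epithet
    assert name.infraspecific == infra
    assert name.conglomerate_epithets == conglom
    assert name.rank is rank


@pytest.mark.parametrize(
    "raw",
    [
        "",
        "   ",
        "Speyeria cybele leto extra",
        "C. ladon",  # abbreviation without context
        "Colias eurytheme/Zerene cesonia",  # cross-genus conglomerate
        "Colias eurytheme/",
    ],
)
def test_parse_rejects_malformed(raw):
    with pytest.raises(NameParseError):
        parse_scientific_name(raw)


def test_abbreviated_genus_expands_against_context():
    name = parse_scientific_name("C. ladon", genus_context="Celastrina")
    assert name.genus == "Celastrina"
    with pytest.raises(NameParseError):
        parse_scientific_name("C. ladon", genus_context="Hesperia")


@pytest.mark.parametrize(
    "raw, canonical",
    [
        ("Celastrina  ladon", "Celastrina ladon"),
        ("Celastrina ladon/neglecta", "Celastrina ladon/neglecta"),
        ("Atrytonopsis edwardsii", "Atrytonopsis edwardsii"),
        ("speyeria CYBELE leto", "Speyeria cybele leto"),
    ],
)
def test_canonical_string(raw, canonical):
    assert canonical_string(parse_scientific_name(raw)) == canonical


@pytest.mark.parametrize(
    "raw",
    [
        "Hesperia comma",
        "Celastrina ladon/neglecta",
        "Speyeria cybele leto",
        "Celastrina   ladon",
    ],
)
def test_parse_canonical_idempotent(raw):
    once = parse_scientific_name(raw)
    twice = parse_scientific_name(canonical_string(once))
    assert canonical_string(twice) == canonical_string(once)
    assert twice.rank is once.rank


# every name string quoted in the deviation-type and complex tables must parse
TABLE_NAMES = [
    "Plebejus melissa",
    "Lycaeides melissa",
    "Zerene cesonia",
    "Hesperia comma colorado",
    "Hesperia colorado",
    "Erionota torus",
    "Erionota thrax",
    "Piruna aea",
    "Piruna cingo",
    "Speyeria cybele leto",
    "Speyeria cybele",
    "Atrytonopsis edwardsi",
    "Atrytonopsis edwardsii",
    "Colias eurytheme/philodice",
    "Kisutam syllis",
    "Celastrina ladon",
    "Celastrina neglecta",
    "Celastrina lucia",
    "Celastrina echo",
    "Celastrina humulus",
    "Celastrina serotina",
    "Celastrina idella",
    "Celastrina ladon/neglecta",
    "Celastrina ladon echo",
]


@pytest.mark.parametrize("raw", TABLE_NAMES)
def test_fixture_vocabulary_parses(raw):
    parse_scientific_name(raw)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("edwardsi", "edwardsii", 1),
        ("ladon", "ladon", 0),
        ("aea", "cingo", 5),  # frozen from the DP oracle
    ],
)
def test_epithet_distance_examples(a, b, expected):
    assert epithet_distance(a, b) == expected
    assert dp_levenshtein(a, b) == expected


@given(EPITHET, EPITHET)
def test_epithet_distance_matches_dp_oracle(a, b):
    assert epithet_distance(a, b) == dp_levenshtein(a, b)


@given(EPITHET, EPITHET, EPITHET)
def test_epithet_distance_metric_axioms(a, b, c):
    dab = epithet_distance(a, b)
    assert dab == epithet_distance(b, a)
    assert (dab == 0) == (a == b)
    assert dab <= epithet_distance(a, c) + epithet_distance(c, b)
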