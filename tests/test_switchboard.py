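"""Concept-graph structure: closures, holders, validation."""

import pytest

from taxoswitch import (
    IntegrityError,
    MappingLookupError,
    add_holder,
    circumscription_of,
    concepts_of,
    parse_scientific_name,
    validate_mapping,
)
from taxoswitch.core import Checklist, MappingFile, Role, SWITCHBOARD_SOURCE, TaxonRecord
from taxoswitch.fixtures import celastrina_fixture
from taxoswitch.switchboard import concept_nodes


def labels(nodes):
    return sorted(n.label for n in nodes)


@pytest.mark.parametrize(
    "source, name, expected",
    [
        ("Cascades", "Celastrina lucia", ["lucia"]),
        ("Iowa", "Celastrina ladon", ["ladon", "neglecta"]),
        ("Illinois", "Celastrina ladon/neglecta", ["ladon", "neglecta"]),
        ("Ohio", "Celastrina neglecta", ["neglecta"]),
        ("Orange County", "Celastrina ladon echo", ["echo"]),
    ],
)
def test_concepts_of_monitored_closure(celastrina, source, name, expected):
    assert labels(concepts_of(celastrina, source, name)) == expected


def test_circumscription_extends_monitored(celastrina):
    # Iowa's single wide name subsumes the unmonitored western segregates
    assert labels(circumscription_of(celastrina, "Iowa", "Celastrina ladon")) == [
        "echo", "humulus", "ladon", "lucia", "neglecta",
    ]
    # a narrow-concept program name circumscribes exactly what it monitors
    assert labels(circumscription_of(celastrina, "Florida", "Celastrina ladon")) == [
        "ladon"
    ]


def test_concepts_of_unknown_name_or_source(celastrina):
    with pytest.raises(MappingLookupError):
        concepts_of(celastrina, "Iowa", "Celastrina echo")
    with pytest.raises(MappingLookupError):
        concepts_of(celastrina, "Nowhere", "Celastrina ladon")


def test_upward_closure_reaches_switchboard_in_two_hops(celastrina):
    for program in celastrina.programs:
        for rec in celastrina.checklist(program).records:
            holder = celastrina[rec.parent_id]
            assert celastrina.checklist(holder.source).role is Role.BASE
            node = celastrina[holder.parent_id]
            assert node.source == SWITCHBOARD_SOURCE


def test_add_holder_duplicates_name_across_concepts():
    mapping = celastrina_fixture()
    nodes = {n.label: n for n in concept_nodes(mapping)}
    name = parse_scientific_name("Celastrina serotina")
    first = add_holder(mapping, "Pelham", name, nodes["serotina"])
    second = add_holder(mapping, "Pelham", name, nodes["idella"])
    assert first.taxon_id != second.taxon_id
    assert first.name.canonical == second.name.canonical
    with pytest.raises(IntegrityError):  # identical (name, concept) refused
        add_holder(mapping, "Pelham", name, nodes["serotina"])
    assert validate_mapping(mapping) == []


def test_holder_addition_is_local(celastrina):
    before = concepts_of(celastrina, "Iowa", "Celastrina ladon")
    mapping = celastrina_fixture()
    nodes = {n.label: n for n in concept_nodes(mapping)}
    add_holder(
        mapping, "OW", parse_scientific_name("Celastrina serotina"), nodes["serotina"]
    )
    after = concepts_of(mapping, "Iowa", "Celastrina ladon")
    assert labels(before) == labels(after)


def test_fixture_is_valid(celastrina):
    assert validate_mapping(celastrina) == []


def _tiny_mapping(extra=None):
    sw = Checklist(SWITCHBOARD_SOURCE, Role.SWITCHBOARD)
    sw.records.append(
        TaxonRecord("T0001", None, parse_scientific_name("Aus bus"), SWITCHBOARD_SOURCE)
    )
    base1 = Checklist("base1", Role.BASE)
    base1.records.append(
        TaxonRecord("T0002", "T0001", parse_scientific_name("Aus bus"), "base1")
    )
    base2 = Checklist("base2", Role.BASE)
    base2.records.append(
        TaxonRecord("T0003", "T0001", parse_scientific_name("Aus bus"), "base2")
    )
    prog = Checklist("prog", Role.PROGRAM, base_id="base1")
    prog.records.append(
        TaxonRecord("T0004", "T0002", parse_scientific_name("Aus bus"), "prog")
    )
    checklists = [sw, base1, base2, prog]
    if extra:
        extra(checklists)
    return MappingFile(checklists)


def test_validation_accepts_minimal_network():
    assert validate_mapping(_tiny_mapping()) == []


def test_validation_flags_cross_base_parent():
    def wrong_base(checklists):
        checklists[3].records.append(
            TaxonRecord(
                "T0005", "T0003", parse_scientific_name("Aus cus"), "prog"
            )
        )

    violations = validate_mapping(_tiny_mapping(wrong_base))
    assert [v.kind for v in violations] == ["cross_role"]


def test_validation_flags_cycle():
    def cycle(checklists):
        checklists[1].records.append(
            TaxonRecord("T0005", "T0006", parse_scientific_name("Aus cus"), "base1")
        )
        checklists[1].records.append(
            TaxonRecord("T0006", "T0005", parse_scientific_name("Aus dus"), "base1")
        )

    violations = validate_mapping(_tiny_mapping(cycle))
    assert [v.kind for v in violations] == ["cycle"]


def test_validation_flags_dangling_parent():
    def dangling(checklists):
        checklists[3].records.append(
            TaxonRecord("T0005", "T0999", parse_scientific_name("Aus cus"), "prog")
        )

    kinds = {v.kind for v in validate_mapping(_tiny_mapping(dangling))}
    assert "dangling_parent" in kinds
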