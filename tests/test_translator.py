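"""Receiver→donor translation and match classification."""

import pytest
from hypothesis import given, strategies as st

from taxoswitch import (
    MappingLookupError,
    MatchType,
    ZERO_MESSAGE,
    check_symmetry,
    classify_match,
    translate,
)
from taxoswitch.translator import DonorCandidate, ReceiverView


@pytest.mark.parametrize(
    "receiver, taxon, donor, expected_type, expected_names",
    [
        ("Iowa", "Celastrina ladon", "Ohio", MatchType.MM,
         ["Celastrina ladon", "Celastrina neglecta"]),
        ("Cascades", "Celastrina echo", "MPG", MatchType.PM, ["Celastrina echo"]),
        ("Colorado", "Celastrina humulus", "Florida", MatchType.ZERO, []),
        ("Ohio", "Celastrina ladon", "Illinois", MatchType.CM_PLUS,
         ["Celastrina ladon/neglecta"]),
        ("Illinois", "Celastrina ladon/neglecta", "Michigan", MatchType.PM,
         ["Celastrina ladon/neglecta"]),
        ("Florida", "Celastrina neglecta", "Ohio", MatchType.PM,
         ["Celastrina neglecta"]),
        ("Florida", "Celastrina ladon", "Ohio", MatchType.CM,
         ["Celastrina ladon"]),
        ("Orange County", "Celastrina ladon echo", "Cascades", MatchType.MM,
         ["Celastrina echo", "Celastrina lucia"]),
        ("Orange County", "Celastrina ladon echo", "Ohio", MatchType.ZERO, []),
    ],
)
def test_translate_fixture_requests(
    celastrina, receiver, taxon, donor, expected_type, expected_names
):
    result = translate(celastrina, receiver, taxon, donor)
    assert result.match_type is expected_type
    assert result.donor_names == expected_names
    if expected_type is MatchType.ZERO:
        assert result.message == ZERO_MESSAGE
    else:
        assert result.message == ""


def test_cm_plus_names_required_siblings(celastrina):
    result = translate(celastrina, "Ohio", "Celastrina ladon", "Illinois")
    assert result.required_receiver_siblings == ["Celastrina neglecta"]
    assert result.flagged


def test_self_translation_is_perfect(celastrina):
    for program in celastrina.programs:
        for taxon in {r.name.canonical for r in celastrina.checklist(program).records}:
            result = translate(celastrina, program, taxon, program)
            assert result.match_type is MatchType.PM
            assert result.donor_names == [taxon]


def test_unknown_receiver_name_is_error_not_zero(celastrina):
    with pytest.raises(MappingLookupError):
        translate(celastrina, "Iowa", "Celastrina echo", "Ohio")


def test_translate_is_deterministic(celastrina):
    first = translate(celastrina, "Iowa", "Celastrina ladon", "Ohio")
    second = translate(celastrina, "Iowa", "Celastrina ladon", "Ohio")
    assert first.to_dict() == second.to_dict()
    assert first.donor_names == sorted(first.donor_names)


def test_mm_concept_conservation(celastrina):
    """For MM, donor names partition the receiver's monitored concepts."""
    from taxoswitch import concepts_of

    result = translate(celastrina, "Iowa", "Celastrina ladon", "Florida")
    assert result.match_type is MatchType.MM
    receiver_set = concepts_of(celastrina, "Iowa", "Celastrina ladon")
    donor_sets = [
        concepts_of(celastrina, "Florida", name) for name in result.donor_names
    ]
    assert set().union(*donor_sets) == receiver_set
    assert sum(len(s) for s in donor_sets) == len(receiver_set)


def test_cm_plus_strictly_contains(celastrina):
    from taxoswitch import concepts_of

    result = translate(celastrina, "Florida", "Celastrina ladon", "Iowa")
    assert result.match_type is MatchType.CM_PLUS
    receiver_set = concepts_of(celastrina, "Florida", "Celastrina ladon")
    donor_set = concepts_of(celastrina, "Iowa", result.donor_names[0])
    assert receiver_set < donor_set


def test_asymmetry_flags(celastrina):
    assert check_symmetry(
        celastrina, "Illinois", "Celastrina ladon/neglecta", "Ohio"
    ) is not None  # MM forward, CM+ back
    assert check_symmetry(celastrina, "Cascades", "Celastrina echo", "MPG") is None
    assert check_symmetry(
        celastrina, "Orange County", "Celastrina ladon echo", "MPG"
    ) is None  # CM both ways


def test_zero_characterization(celastrina):
    """ZERO exactly when no donor data fall inside the receiver concept,
    or the donor's pooled unit cannot be rebuilt by the receiver."""
    from taxoswitch import circumscription_of, concepts_of

    for receiver in celastrina.programs:
        taxa = {r.name.canonical for r in celastrina.checklist(receiver).records}
        for donor in celastrina.programs:
            if donor == receiver:
                continue
            donor_names = {
                r.name.canonical for r in celastrina.checklist(donor).records
            }
            for taxon in taxa:
                result = translate(celastrina, receiver, taxon, donor)
                overlap = any(
                    concepts_of(celastrina, donor, dn)
                    & circumscription_of(celastrina, receiver, taxon)
                    for dn in donor_names
                )
                if not overlap:
                    assert result.match_type is MatchType.ZERO


# --- classify_match against a tiny in-test enumeration oracle ------------


def _enumerate_expected(receiver, candidates):
    """Straight-line restatement of the classification contract."""
    R = set(receiver.circumscription)
    cands = [c for c in candidates if set(c.monitored) & R]
    if not cands:
        return "Zero"
    lumps = [c for c in cands if set(c.monitored) - R]
    if lumps:
        if len(cands) > 1:
            return "error"
        extra = set(lumps[0].monitored) - R
        covered = set()
        for _, mon in receiver.sibling_monitored:
            covered |= set(mon)
        return "CM+" if extra <= covered else "Zero"
    if len(cands) >= 2:
        return "MM"
    sole = cands[0]
    if not (set(sole.monitored) & set(receiver.monitored)
            or set(sole.circumscription) <= R):
        return "Zero"
    if sole.name == receiver.name and set(sole.circumscription) == R:
        return "PM"
    return "CM"


concept_sets = st.sets(st.sampled_from("abcdefg"), min_size=0, max_size=4)


@given(
    rx=st.sets(st.sampled_from("abcdefg"), min_size=1, max_size=4),
    extra_circ=concept_sets,
    cand_sets=st.lists(concept_sets, min_size=0, max_size=3),
    sib=concept_sets,
    same_name=st.booleans(),
)
def test_classify_match_agrees_with_enumeration(rx, extra_circ, cand_sets, sib, same_name):
    receiver = ReceiverView(
        name="Aus bus",
        monitored=frozenset(rx),
        circumscription=frozenset(rx | extra_circ),
        sibling_monitored=(("Aus cus", frozenset(sib)),),
    )
    candidates = [
        DonorCandidate(
            name="Aus bus" if same_name and i == 0 else "Aus d%d" % i,
            monitored=frozenset(s),
            circumscription=frozenset(s),
        )
        for i, s in enumerate(cand_sets)
    ]
    expected = _enumerate_expected(receiver, candidates)
    if expected == "error":
        from taxoswitch import ClassificationError

        with pytest.raises(ClassificationError):
            classify_match(receiver, candidates)
    else:
        mtype, names, _ = classify_match(receiver, candidates)
        assert mtype.value == expected
        assert (mtype is MatchType.ZERO) == (names == [])
        assert (mtype is MatchType.MM) == (len(names) >= 2)
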