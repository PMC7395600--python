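"""Checklist alignment and discrepancy typing."""

import pytest

from taxoswitch import (
    CurationEntry,
    CurationError,
    CurationTable,
    DiscrepancyCode,
    DiscrepancyType,
    SSubtype,
    align_checklists,
    classify_pair,
    summarize,
)
from taxoswitch.diff_engine import name_view, read_curation, write_curation
from taxoswitch.fixtures import SyntheticSpec, synthesize
from tests.conftest import make_checklist


def codes(discrepancies):
    return sorted(d.dtype.code.value for d in discrepancies)


def align_codes(a_names, b_names, curation=None):
    res = align_checklists(
        make_checklist(a_names, "A"), make_checklist(b_names, "B"), curation
    )
    return res, codes(res.discrepancies())


def test_identical_lists_align_cleanly():
    names = [
        "Hesperia comma",
        "Colias eurytheme",
        "Colias philodice",
        "Speyeria cybele",
        "Piruna aea",
    ]
    res, cs = align_codes(names, list(names))
    assert len(res.pairs) == 5
    assert cs == []
    assert not res.unmatched_left and not res.unmatched_right


def test_spelling_deviation_detected():
    res, cs = align_codes(["Atrytonopsis edwardsi"], ["Atrytonopsis edwardsii"])
    assert cs == ["L"]


def test_genus_deviation_detected():
    res, cs = align_codes(["Plebejus melissa"], ["Lycaeides melissa"])
    assert cs == ["G"]


def test_synonym_requires_curation():
    _, cs = align_codes(["Piruna cingo"], ["Piruna aea"])
    assert cs == ["U", "U"]  # without curation the names stay unmatched
    table = CurationTable(
        [
            CurationEntry(
                "A", "Piruna cingo", "B", "Piruna aea",
                DiscrepancyType(DiscrepancyCode.S, SSubtype.SYNONYM),
            )
        ]
    )
    res, cs = align_codes(["Piruna cingo"], ["Piruna aea"], table)
    assert cs == ["S"]
    (pair,) = res.pairs
    assert pair.discrepancies[0].dtype.s_subtype is SSubtype.SYNONYM


def test_conglomerate_matches_two_names():
    res, cs = align_codes(
        ["Colias eurytheme/philodice"], ["Colias eurytheme", "Colias philodice"]
    )
    assert cs == ["C"]
    (pair,) = res.pairs
    assert len(pair.right) == 2


def test_unmatched_taxon():
    res, cs = align_codes(["Kisutam syllis", "Hesperia comma"], ["Hesperia comma"])
    assert cs == ["U"]
    assert [r.name.canonical for r in res.unmatched_left] == ["Kisutam syllis"]


def test_subspecies_promotion_candidate():
    _, cs = align_codes(["Hesperia comma colorado"], ["Hesperia colorado"])
    assert cs == ["S"]


def test_subspecies_use_candidate():
    _, cs = align_codes(["Speyeria cybele leto"], ["Speyeria cybele"])
    assert cs == ["S"]


def test_classify_pair_symmetric_for_g_l_s():
    table = CurationTable(
        [
            CurationEntry(
                "A", "Piruna cingo", "B", "Piruna aea",
                DiscrepancyType(DiscrepancyCode.S, SSubtype.SYNONYM),
            )
        ]
    )
    cases = [
        ("Plebejus melissa", "Lycaeides melissa"),
        ("Atrytonopsis edwardsi", "Atrytonopsis edwardsii"),
        ("Piruna cingo", "Piruna aea"),
    ]
    for left, right in cases:
        (l,) = make_checklist([left], "A").records
        (r,) = make_checklist([right], "B").records
        fwd = [t.code for t in classify_pair(l, r, table)]
        rev = [t.code for t in classify_pair(r, l, table)]
        assert fwd == rev


def test_classify_pair_one_sided_is_unmatched():
    (rec,) = make_checklist(["Kisutam syllis"], "A").records
    assert [t.code.value for t in classify_pair(rec, None)] == ["U"]
    assert [t.code.value for t in classify_pair(None, rec)] == ["U"]


def test_curation_contradiction_rejected():
    table = CurationTable()
    table.add(
        CurationEntry("A", "x a", "B", "x b", DiscrepancyType(DiscrepancyCode.S))
    )
    with pytest.raises(CurationError):
        table.add(
            CurationEntry("A", "x a", "B", "x b", DiscrepancyType(DiscrepancyCode.G))
        )


def test_curation_entry_absent_from_both_lists_errors():
    table = CurationTable(
        [CurationEntry("A", "Piruna cingo", "B", "Piruna aea",
                       DiscrepancyType(DiscrepancyCode.S))]
    )
    with pytest.raises(CurationError):
        align_checklists(
            make_checklist(["Hesperia comma"], "A"),
            make_checklist(["Hesperia comma"], "B"),
            table,
        )


def test_subfamily_deviation_counted_per_descendant():
    a = make_checklist(
        ["Polyommatinae", "Plebejus melissa", "Celastrina ladon"], "A"
    )
    b = make_checklist(
        ["Lycaeninae", "Plebejus melissa", "Celastrina ladon"], "B"
    )
    res = align_checklists(a, b)
    f = [d for d in res.discrepancies() if d.dtype.code is DiscrepancyCode.F]
    assert len(f) == 2  # one per descendant species
    # but F stays out of the species-level summary
    assert "F" not in summarize(res).columns


def test_partition_property():
    res = align_checklists(
        make_checklist(
            ["Hesperia comma", "Plebejus melissa", "Kisutam syllis"], "A"
        ),
        make_checklist(
            ["Hesperia comma", "Lycaeides melissa", "Piruna aea"], "B"
        ),
    )
    n_left = sum(len(p.left) for p in res.pairs) + len(res.unmatched_left)
    n_right = sum(len(p.right) for p in res.pairs) + len(res.unmatched_right)
    assert n_left == 3 and n_right == 3


def test_summary_counts_and_percentages():
    res, _ = align_codes(
        ["Atrytonopsis edwardsi", "Plebejus melissa", "Kisutam syllis",
         "Hesperia comma"],
        ["Atrytonopsis edwardsii", "Lycaeides melissa", "Hesperia comma"],
    )
    row = summarize(res).iloc[0]
    assert (row["G"], row["L"], row["U"], row["total"]) == (1, 1, 1, 3)
    assert row["max_species"] == 4
    assert row["total_pct"] == 75.0  # 3 of 4, one decimal place


@pytest.mark.parametrize("seed", [11, 42])
def test_synthetic_injection_recovered_exactly(seed):
    """Alignment recovers the generator's injected G/L/C/U counts exactly,
    and S too once the injected synonym curation is supplied."""
    spec = SyntheticSpec(
        seed=seed,
        n_concepts=40,
        n_base_lists=2,
        n_programs=4,
        rates={"G": 0.06, "S": 0.06, "L": 0.06, "C": 0.04, "U": 0.06},
        lump_rate=0.2,
    )
    mapping, truth = synthesize(spec)
    for program, base in truth.base_of.items():
        res = align_checklists(
            name_view(mapping.checklist(program)),
            name_view(mapping.checklist(base)),
            truth.curation,
        )
        row = summarize(res).iloc[0]
        for code in "GLCUS":
            assert row[code] == truth.injected[program][code], (program, code)


def test_curation_roundtrip(tmp_path):
    table = CurationTable(
        [
            CurationEntry(
                "A", "Piruna cingo", "B", "Piruna aea",
                DiscrepancyType(DiscrepancyCode.S, SSubtype.SYNONYM), "note",
            ),
            CurationEntry(
                "A", "Plebejus melissa", "B", "Lycaeides melissa",
                DiscrepancyType(DiscrepancyCode.G),
            ),
        ]
    )
    path = write_curation(table, tmp_path / "cur.csv")
    again = read_curation(path)
    assert len(again) == 2
    assert again.lookup("Piruna cingo", "Piruna aea").dtype.s_subtype is SSubtype.SYNONYM
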