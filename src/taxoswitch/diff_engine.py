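"""Pairwise checklist alignment and discrepancy typing.

Two checklists of the same fauna rarely disagree in only one way. The
observed deviation types are:

``F``
    subfamily-name deviation (higher classification only; counted per
    descendant taxon and excluded from species-level summaries);
``G``
    genus-name deviation (same epithet placed in different genera);
``S``
    species-epithet deviation — subspecies promotion, misdetermination,
    alternate synonym, or differing subspecies use;
``L``
    spelling variants of the same epithet;
``C``
    conglomerate — one list pools two taxa the other keeps separate;
``U``
    unmatched taxon — present on one list under no name at all.

Alignment is exact-name first, then curated pairs, then conservative
heuristics. Spelling variants and genus swaps can be proposed
automatically; synonym-type S deviations are inherently curatorial (the
original determinations were resolved by asking the program directors),
so without a curation entry such records stay unmatched rather than being
guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .core import Checklist, CurationError, FormatError, TaxonRecord
from .names import Rank, epithet_distance

__all__ = [
    "DiscrepancyCode",
    "SSubtype",
    "DiscrepancyType",
    "Discrepancy",
    "CurationEntry",
    "CurationTable",
    "AlignedPair",
    "AlignmentResult",
    "align_checklists",
    "classify_pair",
    "summarize",
    "read_curation",
    "write_curation",
]


class DiscrepancyCode(str, Enum):
    F = "F"  # subfamily
    G = "G"  # genus
    S = "S"  # species epithet
    L = "L"  # spelling
    C = "C"  # conglomerate
    U = "U"  # unmatched


class SSubtype(str, Enum):
    PROMOTION = "promotion"
    MISDETERMINATION = "misdetermination"
    SYNONYM = "synonym"
    SUBSPECIES_USE = "subspecies_use"


@dataclass(frozen=True)
class DiscrepancyType:
    code: DiscrepancyCode
    s_subtype: SSubtype | None = None

    def __post_init__(self) -> None:
        if self.s_subtype is not None and self.code is not DiscrepancyCode.S:
            raise ValueError("s_subtype only applies to code S")

    def __str__(self) -> str:  # pragma: no cover
        if self.s_subtype:
            return "%s(%s)" % (self.code.value, self.s_subtype.value)
        return self.code.value


@dataclass(frozen=True)
class Discrepancy:
    left: tuple[str, str] | None  # (source, canonical name)
    right: tuple[str, str] | None
    dtype: DiscrepancyType
    note: str = ""

    def __post_init__(self) -> None:
        if self.left is None and self.right is None:
            raise ValueError("a discrepancy needs at least one side")
        one_sided = (self.left is None) != (self.right is None)
        if one_sided != (self.dtype.code is DiscrepancyCode.U):
            raise ValueError("U discrepancies are exactly the one-sided ones")


@dataclass(frozen=True)
class CurationEntry:
    left_source: str
    left_name: str
    right_source: str
    right_name: str
    dtype: DiscrepancyType
    note: str = ""

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.left_name.casefold(), self.right_name.casefold()))


class CurationTable:
    """Curator-supplied pairings; contradictory entries are rejected."""

    def __init__(self, entries: list[CurationEntry] | None = None):
        self.entries: list[CurationEntry] = []
        self._by_pair: dict[frozenset[str], CurationEntry] = {}
        for entry in entries or []:
            self.add(entry)

    def add(self, entry: CurationEntry) -> None:
        existing = self._by_pair.get(entry.pair_key)
        if existing is not None and existing.dtype != entry.dtype:
            raise CurationError(
                "contradictory curation for pair %s: %s vs %s"
                % (sorted(entry.pair_key), existing.dtype, entry.dtype)
            )
        if existing is None:
            self.entries.append(entry)
            self._by_pair[entry.pair_key] = entry

    def lookup(self, left_name: str, right_name: str) -> CurationEntry | None:
        return self._by_pair.get(
            frozenset((left_name.casefold(), right_name.casefold()))
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AlignedPair:
    """A matched group: usually 1:1, 1:2 for conglomerates."""

    left: list[TaxonRecord]
    right: list[TaxonRecord]
    discrepancies: list[Discrepancy] = field(default_factory=list)


@dataclass
class AlignmentResult:
    left_source: str
    right_source: str
    pairs: list[AlignedPair]
    unmatched_left: list[TaxonRecord]
    unmatched_right: list[TaxonRecord]
    curation: CurationTable
    ambiguous: list[str] = field(default_factory=list)

    def discrepancies(self) -> list[Discrepancy]:
        out = [d for p in self.pairs for d in p.discrepancies]
        for rec in self.unmatched_left:
            out.append(
                Discrepancy(
                    (self.left_source, rec.name.canonical),
                    None,
                    DiscrepancyType(DiscrepancyCode.U),
                )
            )
        for rec in self.unmatched_right:
            out.append(
                Discrepancy(
                    None,
                    (self.right_source, rec.name.canonical),
                    DiscrepancyType(DiscrepancyCode.U),
                )
            )
        return out


# ---------------------------------------------------------------------------
# classification


def _name_pair_types(
    left: TaxonRecord, right: TaxonRecord, entry: CurationEntry | None
) -> list[DiscrepancyType]:
    """All deviation types applicable to a matched record pair."""
    ln, rn = left.name, right.name
    out: list[DiscrepancyType] = []
    if ln.key == rn.key:
        return out
    if entry is not None and entry.dtype.code is DiscrepancyCode.S:
        out.append(entry.dtype)
    if ln.genus.casefold() != rn.genus.casefold():
        out.append(DiscrepancyType(DiscrepancyCode.G))
    le, re_ = ln.epithet, rn.epithet
    if le and re_ and le != re_:
        if _is_spelling_variant(le, re_):
            out.append(DiscrepancyType(DiscrepancyCode.L))
        elif not any(t.code is DiscrepancyCode.S for t in out):
            # same-genus epithet swap without a spelling relationship:
            # a species-level deviation; subtype only via curation
            sub = _infer_s_subtype(left, right)
            out.append(DiscrepancyType(DiscrepancyCode.S, sub))
    if ln.infraspecific != rn.infraspecific and le == re_:
        if not any(t.code is DiscrepancyCode.S for t in out):
            out.append(
                DiscrepancyType(DiscrepancyCode.S, SSubtype.SUBSPECIES_USE)
            )
    if ln.epithet and rn.infraspecific and ln.epithet == rn.infraspecific:
        if not any(t.code is DiscrepancyCode.S for t in out):
            out.append(DiscrepancyType(DiscrepancyCode.S, SSubtype.PROMOTION))
    if rn.epithet and ln.infraspecific and rn.epithet == ln.infraspecific:
        if not any(t.code is DiscrepancyCode.S for t in out):
            out.append(DiscrepancyType(DiscrepancyCode.S, SSubtype.PROMOTION))
    return out


def _infer_s_subtype(left: TaxonRecord, right: TaxonRecord) -> SSubtype | None:
    ln, rn = left.name, right.name
    if ln.rank is Rank.SUBSPECIES or rn.rank is Rank.SUBSPECIES:
        if ln.epithet == rn.infraspecific or rn.epithet == ln.infraspecific:
            return SSubtype.PROMOTION
    return None


def _is_spelling_variant(a: str, b: str) -> bool:
    """Epithet distance <= 2 with the first two characters identical."""
    return a[:2] == b[:2] and epithet_distance(a, b) <= 2


def classify_pair(
    left: TaxonRecord | list[TaxonRecord] | None,
    right: TaxonRecord | list[TaxonRecord] | None,
    curation: CurationTable | None = None,
) -> list[DiscrepancyType]:
    """Classify one matched group (or a one-sided unmatched record).

    Returns every applicable deviation type; an exact match returns an
    empty list. Symmetric under argument swap for G, L and S.
    """
    lefts = _as_list(left)
    rights = _as_list(right)
    if not lefts and not rights:
        raise ValueError("classify_pair needs at least one side")
    if not lefts or not rights:
        return [DiscrepancyType(DiscrepancyCode.U)]
    if len(lefts) > 1 or len(rights) > 1:
        return [DiscrepancyType(DiscrepancyCode.C)]
    l, r = lefts[0], rights[0]
    if l.name.rank is Rank.CONGLOMERATE or r.name.rank is Rank.CONGLOMERATE:
        if l.name.key != r.name.key:
            return [DiscrepancyType(DiscrepancyCode.C)]
    entry = curation.lookup(l.name.canonical, r.name.canonical) if curation else None
    return _name_pair_types(l, r, entry)


def _as_list(x) -> list[TaxonRecord]:
    if x is None:
        return []
    if isinstance(x, TaxonRecord):
        return [x]
    return list(x)


# ---------------------------------------------------------------------------
# alignment


def name_view(cl: Checklist) -> Checklist:
    """A checklist reduced to one record per canonical name.

    Mapping-file program sections carry one row per holder link, so a
    name spanning several concepts appears several times; alignment and
    diff summaries operate on the user-facing name list.
    """
    seen: set[str] = set()
    records = []
    for rec in cl.records:
        if rec.name.key not in seen:
            seen.add(rec.name.key)
            records.append(rec)
    return Checklist(cl.source_id, cl.role, records, base_id=cl.base_id)


def _species_like(rec: TaxonRecord) -> bool:
    return rec.name.rank in (Rank.SPECIES, Rank.SUBSPECIES, Rank.CONGLOMERATE)


def align_checklists(
    a: Checklist, b: Checklist, curation: CurationTable | None = None
) -> AlignmentResult:
    """Align two checklists and type every difference.

    Pairing order: exact canonical match, curation entries, then
    heuristics (spelling variants within a genus, genus swaps on a shared
    epithet, conglomerates whose components match two names, subspecies
    promotion/use patterns). Leftovers are unmatched (U).
    """
    curation = curation or CurationTable()
    left = [r for r in a.records if _species_like(r)]
    right = [r for r in b.records if _species_like(r)]
    f_discrepancies = _subfamily_discrepancies(a, b)

    pairs: list[AlignedPair] = []
    ambiguous: list[str] = []
    used_l: set[int] = set()
    used_r: set[int] = set()

    right_by_key: dict[str, list[int]] = {}
    for j, rec in enumerate(right):
        right_by_key.setdefault(rec.name.key, []).append(j)

    # 1. exact canonical matches
    for i, rec in enumerate(left):
        js = [j for j in right_by_key.get(rec.name.key, []) if j not in used_r]
        if js:
            j = js[0]
            used_l.add(i)
            used_r.add(j)
            pairs.append(AlignedPair([rec], [right[j]], []))

    # 2. curation entries (only those addressed to this source pair;
    # a shared table may cover many pairwise comparisons)
    pair_sources = {a.source_id, b.source_id}
    for entry in curation.entries:
        entry_sources = {entry.left_source, entry.right_source}
        if entry_sources and entry_sources - pair_sources:
            continue
        l_idx = _find_by_name(left, entry.left_name, used_l)
        r_idx = _find_by_name(right, entry.right_name, used_r)
        if l_idx is None and r_idx is None:
            l_sw = _find_by_name(left, entry.right_name, used_l)
            r_sw = _find_by_name(right, entry.left_name, used_r)
            if l_sw is None and r_sw is None:
                if not _present_anywhere(left, right, entry):
                    raise CurationError(
                        "curation entry (%s / %s) references names absent "
                        "from both lists" % (entry.left_name, entry.right_name)
                    )
                continue  # names exist but already matched exactly
            l_idx, r_idx = l_sw, r_sw
        if l_idx is None or r_idx is None:
            continue
        used_l.add(l_idx)
        used_r.add(r_idx)
        l, r = left[l_idx], right[r_idx]
        pairs.append(
            AlignedPair(
                [l],
                [r],
                _wrap(
                    a.source_id,
                    b.source_id,
                    l,
                    r,
                    classify_pair(l, r, curation),
                    entry.note,
                ),
            )
        )

    # 3a. conglomerate resolution
    for i, rec in enumerate(left):
        if i in used_l or rec.name.rank is not Rank.CONGLOMERATE:
            continue
        match = _conglomerate_partners(rec, right, used_r)
        if match:
            used_l.add(i)
            used_r.update(match)
            group = [right[j] for j in match]
            disc = Discrepancy(
                (a.source_id, rec.name.canonical),
                (b.source_id, " + ".join(g.name.canonical for g in group)),
                DiscrepancyType(DiscrepancyCode.C),
            )
            pairs.append(AlignedPair([rec], group, [disc]))
    for j, rec in enumerate(right):
        if j in used_r or rec.name.rank is not Rank.CONGLOMERATE:
            continue
        match = _conglomerate_partners(rec, left, used_l)
        if match:
            used_r.add(j)
            used_l.update(match)
            group = [left[i] for i in match]
            disc = Discrepancy(
                (a.source_id, " + ".join(g.name.canonical for g in group)),
                (b.source_id, rec.name.canonical),
                DiscrepancyType(DiscrepancyCode.C),
            )
            pairs.append(AlignedPair(group, [rec], [disc]))

    # 3b. spelling / genus-swap / subspecies heuristics
    for i, rec in enumerate(left):
        if i in used_l:
            continue
        candidates = _heuristic_candidates(rec, right, used_r)
        if not candidates:
            continue
        best = min(c[1] for c in candidates)
        top = [c for c in candidates if c[1] == best]
        if len(top) > 1:
            ambiguous.append(
                "%r matches %s equally well; curation required"
                % (rec.name.canonical, [right[j].name.canonical for j, _ in top])
            )
            continue
        j = top[0][0]
        used_l.add(i)
        used_r.add(j)
        r = right[j]
        pairs.append(
            AlignedPair(
                [rec],
                [r],
                _wrap(
                    a.source_id,
                    b.source_id,
                    rec,
                    r,
                    classify_pair(rec, r, curation),
                ),
            )
        )

    unmatched_left = [r for i, r in enumerate(left) if i not in used_l]
    unmatched_right = [r for j, r in enumerate(right) if j not in used_r]
    for pair in pairs:
        pair.discrepancies.extend(
            d
            for d in f_discrepancies
            if d.left and d.left[1] in {x.name.canonical for x in pair.left}
        )
    return AlignmentResult(
        a.source_id, b.source_id, pairs, unmatched_left, unmatched_right,
        curation, ambiguous,
    )


def _wrap(ls, rs, l, r, types, note=""):
    return [
        Discrepancy((ls, l.name.canonical), (rs, r.name.canonical), t, note)
        for t in types
    ]


def _find_by_name(records, name, used) -> int | None:
    key = " ".join(name.split()).casefold()
    for i, rec in enumerate(records):
        if i not in used and rec.name.key == key:
            return i
    return None


def _present_anywhere(left, right, entry) -> bool:
    keys = {entry.left_name.casefold(), entry.right_name.casefold()}
    names = {r.name.key for r in left} | {r.name.key for r in right}
    return bool(keys & names)


def _conglomerate_partners(rec, others, used) -> list[int] | None:
    wanted = {
        (rec.name.genus.casefold(), e) for e in rec.name.conglomerate_epithets
    }
    found: list[int] = []
    for j, other in enumerate(others):
        if j in used or not other.name.epithet:
            continue
        key = (other.name.genus.casefold(), other.name.epithet)
        if key in wanted:
            found.append(j)
            wanted.discard(key)
    return found if len(found) >= 2 else None


def _heuristic_candidates(rec, others, used) -> list[tuple[int, int]]:
    """(index, cost) candidates for a leftover record."""
    out = []
    n = rec.name
    if not n.epithet:
        return out
    for j, other in enumerate(others):
        if j in used:
            continue
        o = other.name
        if not o.epithet:
            continue
        same_genus = n.genus.casefold() == o.genus.casefold()
        if same_genus and _is_spelling_variant(n.epithet, o.epithet):
            out.append((j, epithet_distance(n.epithet, o.epithet)))
        elif not same_genus and n.epithet == o.epithet:
            out.append((j, 0))
        elif same_genus and (
            n.epithet == o.infraspecific or o.epithet == n.infraspecific
        ):
            out.append((j, 1))  # promotion pattern
        elif same_genus and n.epithet == o.epithet:
            out.append((j, 1))  # subspecies-use pattern
    return out


def _subfamily_discrepancies(a: Checklist, b: Checklist) -> list[Discrepancy]:
    """F deviations, counted per descendant species, when both lists
    carry subfamily headers (a run of species under a subfamily row)."""
    fa = _subfamily_of(a)
    fb = _subfamily_of(b)
    if not fa or not fb:
        return []
    out = []
    for name, sub_a in fa.items():
        sub_b = fb.get(name)
        if sub_b is not None and sub_a.casefold() != sub_b.casefold():
            out.append(
                Discrepancy(
                    (a.source_id, name),
                    (b.source_id, name),
                    DiscrepancyType(DiscrepancyCode.F),
                    "%s vs %s" % (sub_a, sub_b),
                )
            )
    return out


def _subfamily_of(cl: Checklist) -> dict[str, str]:
    current: str | None = None
    out: dict[str, str] = {}
    for rec in cl.records:
        if rec.name.rank is Rank.SUBFAMILY:
            current = rec.name.canonical
        elif _species_like(rec) and current is not None:
            out[rec.name.canonical] = current
    return out


# ---------------------------------------------------------------------------
# summaries


def summarize(
    alignment: AlignmentResult,
    max_species: int | None = None,
    include_f: bool = False,
) -> pd.DataFrame:
    """Deviation counts by type, with percentages of the larger list.

    Subfamily (F) deviations are excluded by default: program lists hang
    off lower-level taxonomy, so a renamed subfamily inflates counts
    without affecting data integration. Percentages are rounded to one
    decimal place.
    """
    counts: dict[str, int] = {c.value: 0 for c in DiscrepancyCode}
    for disc in alignment.discrepancies():
        counts[disc.dtype.code.value] += 1
    if not include_f:
        counts.pop("F")
    if max_species is None:
        n_left = sum(len(p.left) for p in alignment.pairs) + len(
            alignment.unmatched_left
        )
        n_right = sum(len(p.right) for p in alignment.pairs) + len(
            alignment.unmatched_right
        )
        max_species = max(n_left, n_right)
    total = sum(counts.values())
    row = {"pair": "%s/%s" % (alignment.left_source, alignment.right_source)}
    for code, cnt in counts.items():
        row[code] = cnt
        row["%s_pct" % code] = (
            round(100.0 * cnt / max_species, 1) if max_species else 0.0
        )
    row["total"] = total
    row["total_pct"] = round(100.0 * total / max_species, 1) if max_species else 0.0
    row["max_species"] = max_species
    return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# curation-table I/O

_CURATION_COLUMNS = [
    "leftSource",
    "leftName",
    "rightSource",
    "rightName",
    "dtype",
    "sSubtype",
    "note",
]


def read_curation(path: str | Path) -> CurationTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CURATION_COLUMNS if c not in df.columns and c != "note"]
    if missing:
        raise FormatError("curation file missing columns: %s" % missing)
    table = CurationTable()
    for rec in df.itertuples(index=False):
        sub = getattr(rec, "sSubtype", "").strip()
        table.add(
            CurationEntry(
                rec.leftSource,
                rec.leftName,
                rec.rightSource,
                rec.rightName,
                DiscrepancyType(
                    DiscrepancyCode(rec.dtype.strip()),
                    SSubtype(sub) if sub else None,
                ),
                getattr(rec, "note", ""),
            )
        )
    return table


def write_curation(table: CurationTable, path: str | Path) -> Path:
    rows = [
        {
            "leftSource": e.left_source,
            "leftName": e.left_name,
            "rightSource": e.right_source,
            "rightName": e.right_name,
            "dtype": e.dtype.code.value,
            "sSubtype": e.dtype.s_subtype.value if e.dtype.s_subtype else "",
            "note": e.note,
        }
        for e in table.entries
    ]
    pd.DataFrame(rows, columns=_CURATION_COLUMNS).to_csv(path, index=False)
    return Path(path)
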