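"""Full-catalogue alignment statistics.

These checks operate on the complete base-authority catalogues and the
ten program checklists, which are *not* bundled with the package (they
are large third-party lists). When the files are supplied locally, the
functions below recompute the headline alignment statistics: the number
of names identical across all base treatments, per-pair deviation totals
by type, and the cross-program name census.

Expected local layout (all plain checklist CSVs with a
``scientificName`` column, plus an optional curation CSV)::

    data/supplementary/
        base_NABA.csv  base_OW.csv  base_Pelham.csv  base_ITIS.csv
        base_curation.csv
        program_<name>.csv ...
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

from .checklist_io import read_checklist
from .diff_engine import CurationTable, align_checklists, read_curation, summarize

__all__ = ["base_alignment_stats", "program_alignment_stats", "SUPPLEMENTARY_DIR"]

#: Conventional location, relative to a working directory / repo root.
SUPPLEMENTARY_DIR = Path("data") / "supplementary"


def base_alignment_stats(
    base_paths: dict[str, Path], curation_path: Path | None = None
) -> dict:
    """Identical-name count across all base lists plus pairwise deviation
    summaries (one row per list pair, counts by type G/S/L/C/U)."""
    lists = {
        name: read_checklist(path, name) for name, path in sorted(base_paths.items())
    }
    curation = read_curation(curation_path) if curation_path else CurationTable()
    name_sets = {
        name: {r.name.key for r in cl.records} for name, cl in lists.items()
    }
    identical = set.intersection(*name_sets.values()) if name_sets else set()
    pairwise = {}
    for a, b in combinations(sorted(lists), 2):
        row = summarize(align_checklists(lists[a], lists[b], curation)).iloc[0]
        pairwise["%s/%s" % (a, b)] = {
            code: int(row[code]) for code in ("G", "S", "L", "C", "U")
        } | {"total": int(row["total"])}
    return {"identical_names": len(identical), "pairwise": pairwise}


def program_alignment_stats(program_paths: dict[str, Path]) -> dict:
    """Cross-program name census: distinct names, names matching exactly
    in two or more programs, names confined to a single program."""
    name_lists = {
        name: {r.name.key for r in read_checklist(path, name).records}
        for name, path in sorted(program_paths.items())
    }
    all_names: dict[str, int] = {}
    for names in name_lists.values():
        for n in names:
            all_names[n] = all_names.get(n, 0) + 1
    distinct = len(all_names)
    shared_exact = sum(1 for c in all_names.values() if c >= 2)
    single_program = sum(1 for c in all_names.values() if c == 1)
    return {
        "distinct_names": distinct,
        "exact_cross_program_matches": shared_exact,
        "single_program_names": single_program,
    }
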