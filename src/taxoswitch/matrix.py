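"""Species-concept integration matrices and their comparison.

An integration matrix is the complete receiver-taxon × donor-program grid
of translation outcomes for one species complex: each off-diagonal cell
holds the match code (PM / CM / MM / CM+ / Zero) plus a flag marker, the
diagonal is marked ``X`` (self-comparisons are never translated). The
expected matrix for a complex — curated by hand from the programs'
declared interpretations — doubles as the regression harness for the
translator: ``compare_matrix`` reports cell-by-cell agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import FormatError, MappingFile, MappingLookupError
from .switchboard import concept_nodes, _ascend
from .translator import translate

__all__ = [
    "Cell",
    "IntegrationMatrix",
    "MatrixComparison",
    "build_matrix",
    "compare_matrix",
    "read_expected_matrix",
    "write_matrix_csv",
    "render_matrix",
]

#: Aliases accepted when reading expected-matrix files produced under
#: older code conventions. "ABS" marks a receiver row that would never
#: issue the request and is dropped on read.
_CODE_ALIASES = {
    "EM": "CM",
    "EM-S": "CM",
    "COM": "CM+",
    "Z": "Zero",
    "ZERO": "Zero",
    "PM": "PM",
    "CM": "CM",
    "CM+": "CM+",
    "MM": "MM",
    "X": "X",
}


@dataclass(frozen=True)
class Cell:
    code: str  # PM | CM | CM+ | MM | Zero | X
    flagged: bool = False

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.code + ("*" if self.flagged and self.code != "X" else "")


@dataclass
class IntegrationMatrix:
    complex_id: str
    rows: list[tuple[str, str]]  # (receiver program, receiver taxon)
    columns: list[str]  # donor programs
    cells: dict[tuple[str, str, str], Cell] = field(default_factory=dict)

    def cell(self, program: str, taxon: str, donor: str) -> Cell:
        return self.cells[(program, taxon, donor)]

    def off_diagonal(self):
        for program, taxon in self.rows:
            for donor in self.columns:
                if donor != program:
                    yield (program, taxon, donor), self.cells[(program, taxon, donor)]


@dataclass
class MatrixComparison:
    total_cells: int
    agreeing: int
    mismatches: list[tuple[tuple[str, str, str], Cell, Cell]]

    @property
    def agreement_pct(self) -> float:
        return 100.0 * self.agreeing / self.total_cells if self.total_cells else 100.0


def _complex_members(mapping: MappingFile, complex_id: str) -> set[str]:
    ids = {n.concept_id for n in concept_nodes(mapping, complex_id)}
    if not ids:
        raise MappingLookupError("unknown or empty complex %r" % complex_id)
    return ids


def build_matrix(
    mapping: MappingFile,
    complex_id: str,
    program_order: list[str] | None = None,
) -> IntegrationMatrix:
    """Fill the full matrix for one complex by running the translator on
    every off-diagonal (receiver taxon, donor) combination."""
    members = _complex_members(mapping, complex_id)
    order = program_order if program_order is not None else mapping.programs
    rows: list[tuple[str, str]] = []
    for program in order:
        cl = mapping.checklist(program)
        seen: list[str] = []
        for rec in cl.records:
            concept = _ascend(mapping, rec).concept_id
            if concept in members and rec.name.canonical not in seen:
                seen.append(rec.name.canonical)
        rows.extend((program, taxon) for taxon in seen)
    if not rows:
        raise MappingLookupError(
            "no program monitors any member of complex %r" % complex_id
        )
    matrix = IntegrationMatrix(complex_id, rows, list(order))
    for program, taxon in rows:
        for donor in order:
            if donor == program:
                matrix.cells[(program, taxon, donor)] = Cell("X")
                continue
            res = translate(mapping, program, taxon, donor)
            matrix.cells[(program, taxon, donor)] = Cell(
                res.match_type.value, res.flagged
            )
    return matrix


def compare_matrix(
    actual: IntegrationMatrix, expected: IntegrationMatrix
) -> MatrixComparison:
    """Cell-by-cell comparison on (match code, flag presence) over all
    off-diagonal cells. Shape mismatch is an error, not a disagreement."""
    if set(actual.rows) != set(expected.rows) or set(actual.columns) != set(
        expected.columns
    ):
        raise FormatError(
            "matrix shapes differ: rows %s vs %s / columns %s vs %s"
            % (sorted(actual.rows), sorted(expected.rows),
               actual.columns, expected.columns)
        )
    mismatches = []
    total = 0
    for key, exp_cell in expected.off_diagonal():
        total += 1
        act_cell = actual.cells[key]
        if (act_cell.code, act_cell.flagged) != (exp_cell.code, exp_cell.flagged):
            mismatches.append((key, exp_cell, act_cell))
    return MatrixComparison(total, total - len(mismatches), mismatches)


def read_expected_matrix(path: str | Path) -> IntegrationMatrix:
    """Read an expected-matrix CSV (columns: complexId, receiverProgram,
    receiverTaxon, donorProgram, expectedCode, expectedFlag)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        "complexId",
        "receiverProgram",
        "receiverTaxon",
        "donorProgram",
        "expectedCode",
        "expectedFlag",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError("expected-matrix file missing columns: %s" % missing)
    complexes = sorted(set(df["complexId"]))
    if len(complexes) != 1:
        raise FormatError("expected one complex per file, got %s" % complexes)
    rows: list[tuple[str, str]] = []
    columns: list[str] = []
    cells: dict[tuple[str, str, str], Cell] = {}
    for rec in df.itertuples(index=False):
        code_raw = rec.expectedCode.strip().upper()
        if code_raw == "ABS":
            continue
        try:
            code = _CODE_ALIASES[code_raw]
        except KeyError:
            raise FormatError("unknown match code %r" % rec.expectedCode) from None
        row = (rec.receiverProgram, rec.receiverTaxon)
        if row not in rows:
            rows.append(row)
        if rec.donorProgram not in columns:
            columns.append(rec.donorProgram)
        cells[(rec.receiverProgram, rec.receiverTaxon, rec.donorProgram)] = Cell(
            code, rec.expectedFlag.strip() == "1"
        )
    return IntegrationMatrix(complexes[0], rows, columns, cells)


def write_matrix_csv(
    matrix: IntegrationMatrix,
    path: str | Path,
    expected: IntegrationMatrix | None = None,
) -> Path:
    """Write a matrix in the expected-matrix format (plus actual columns
    when comparing against an expected matrix)."""
    rows = []
    for (program, taxon, donor), cell in sorted(matrix.cells.items()):
        row = {
            "complexId": matrix.complex_id,
            "receiverProgram": program,
            "receiverTaxon": taxon,
            "donorProgram": donor,
            "expectedCode": cell.code,
            "expectedFlag": "1" if cell.flagged else "0",
        }
        if expected is not None:
            exp = expected.cells.get((program, taxon, donor))
            row["actualCode"] = row.pop("expectedCode")
            row["actualFlag"] = row.pop("expectedFlag")
            row["expectedCode"] = exp.code if exp else ""
            row["expectedFlag"] = ("1" if exp.flagged else "0") if exp else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def render_matrix(
    matrix: IntegrationMatrix, abbreviations: dict[str, str] | None = None
) -> str:
    """Plain-text grid; flagged cells carry a ``*`` marker."""
    abbr = abbreviations or {}
    header = ["receiver / donor"] + [abbr.get(c, c) for c in matrix.columns]
    widths = [len(h) for h in header]
    lines = []
    for program, taxon in matrix.rows:
        label = "%s: %s" % (abbr.get(program, program), taxon)
        row = [label] + [
            str(matrix.cells[(program, taxon, donor)]) for donor in matrix.columns
        ]
        widths = [max(w, len(c)) for w, c in zip(widths, row)]
        lines.append(row)
    fmt = "  ".join("%%-%ds" % w for w in widths)
    out = [fmt % tuple(header)]
    out.extend(fmt % tuple(row) for row in lines)
    return "\n".join(out)
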