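"""Alignment containers, Stockholm/FASTA I/O and column-to-target mapping.

Alignments are read with :mod:`Bio.AlignIO` and normalized onto the 5-letter
alphabet ``{A, C, G, U, -}``: DNA ``T`` becomes ``U``, lowercase is
uppercased, and every other symbol (``.``, ``N``, IUPAC degenerate codes)
becomes a gap. When a Stockholm file carries a ``#=GC RF`` reference
annotation, insert columns (``.`` or lowercase in RF) are dropped and the
retained-column mask is recorded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .alphabet import GAP, encode, normalize_sequence
from .errors import AlignmentFormatError, RnaDcaError
from .structures import parse_wuss


@dataclass
class Alignment:
    """An RNA multiple sequence alignment over ``{A, C, G, U, -}``.

    ``consensus_structure`` holds the nested base pairs of the Stockholm
    ``SS_cons`` line as 0-based column pairs; crossing pairs from extended
    WUSS (including pseudoknot letters) live separately in
    ``crossing_pairs`` and never enter the nested set.
    """

    sequence_ids: list[str]
    rows: list[str]
    consensus_structure: list[tuple[int, int]] | None = None
    crossing_pairs: list[tuple[int, int]] = field(default_factory=list)
    column_mask: np.ndarray | None = None  # indices of retained source columns

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no sequences")
        L = len(self.rows[0])
        if L == 0:
            raise AlignmentFormatError("alignment has zero columns")
        if any(len(r) != L for r in self.rows):
            raise AlignmentFormatError("ragged alignment: rows differ in length")
        if len(self.sequence_ids) != len(self.rows):
            raise AlignmentFormatError("sequence_ids and rows differ in length")

    @property
    def M(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @cached_property
    def matrix(self) -> np.ndarray:
        """State-index matrix, shape ``(M, L)``, int8."""
        return encode(self.rows)

    def row(self, sequence_id: str) -> str:
        try:
            return self.rows[self.sequence_ids.index(sequence_id)]
        except ValueError:
            raise LookupError(f"no sequence {sequence_id!r} in alignment") from None


@dataclass
class ColumnMap:
    """Mapping between alignment columns and ungapped target positions.

    ``col_to_pos[c]`` is the 0-based target position of column ``c`` or -1
    where the target row carries a gap; ``pos_to_col`` is its (total) inverse
    on target positions. ``col_to_pos`` is strictly increasing where defined
    and composing the two maps is the identity.
    """

    target_id: str
    target_sequence: str
    col_to_pos: np.ndarray
    pos_to_col: np.ndarray


def build_column_map(aln: Alignment, target_id: str) -> ColumnMap:
    """Build the column/position map for one alignment row."""
    row = aln.row(target_id)
    col_to_pos = np.full(aln.L, -1, dtype=np.int64)
    pos_to_col = []
    seq = []
    for c, ch in enumerate(row):
        if ch != GAP:
            col_to_pos[c] = len(seq)
            pos_to_col.append(c)
            seq.append(ch)
    if not seq:
        raise RnaDcaError(f"target row {target_id!r} is all gaps")
    return ColumnMap(target_id, "".join(seq), col_to_pos,
                     np.array(pos_to_col, dtype=np.int64))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read a Stockholm or aligned-FASTA file into a normalized Alignment.

    Raises :class:`AlignmentFormatError` for empty or ragged input and
    :class:`StructureFormatError` for unbalanced ``SS_cons`` brackets.
    """
    path = Path(path)
    if format is None:
        format = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
            else "fasta"
    if format not in ("stockholm", "fasta"):
        raise AlignmentFormatError(f"unknown alignment format {format!r}")
    try:
        bio = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc

    ids = [rec.id for rec in bio]
    raw_rows = [str(rec.seq) for rec in bio]
    ss_line = bio.column_annotations.get("secondary_structure")
    rf_line = bio.column_annotations.get("reference_annotation")

    keep = None
    if rf_line is not None:
        keep = [c for c, ch in enumerate(rf_line) if ch != "." and not ch.islower()]
        if not keep:
            raise AlignmentFormatError("RF annotation marks every column as insert")
        raw_rows = ["".join(r[c] for c in keep) for r in raw_rows]
        if ss_line is not None:
            ss_line = "".join(ss_line[c] for c in keep)

    rows = [normalize_sequence(r) for r in raw_rows]
    consensus = crossing = None
    if ss_line is not None:
        nested, cross = parse_wuss(ss_line)
        consensus, crossing = nested, cross
    return Alignment(
        sequence_ids=ids,
        rows=rows,
        consensus_structure=consensus,
        crossing_pairs=crossing or [],
        column_mask=None if keep is None else np.array(keep, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_alignment(aln: Alignment, path: str | Path, format: str | None = None,
                    header: str | None = None) -> None:
    """Write FASTA or Stockholm (one sequence per line, no wrapping)."""
    path = Path(path)
    if format is None:
        format = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") \
            else "fasta"
    buf = io.StringIO()
    if format == "fasta":
        for sid, row in zip(aln.sequence_ids, aln.rows):
            buf.write(f">{sid}\n{row}\n")
    elif format == "stockholm":
        buf.write("# STOCKHOLM 1.0\n")
        if header:
            buf.write(f"#=GF CC {header}\n")
        width = max(len(s) for s in aln.sequence_ids) + 2
        width = max(width, len("#=GC SS_cons") + 2)
        for sid, row in zip(aln.sequence_ids, aln.rows):
            buf.write(f"{sid:<{width}}{row}\n")
        if aln.consensus_structure is not None:
            ss = ["."] * aln.L
            for i, j in aln.consensus_structure:
                ss[i], ss[j] = "(", ")"
            # crossing pairs are written with square brackets
            for i, j in aln.crossing_pairs:
                ss[i], ss[j] = "[", "]"
            buf.write(f"{'#=GC SS_cons':<{width}}{''.join(ss)}\n")
        buf.write("//\n")
    else:
        raise AlignmentFormatError(f"unknown alignment format {format!r}")
    path.write_text(buf.getvalue())
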