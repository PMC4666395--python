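"""Secondary-structure containers, WUSS/dot-bracket/CT parsing and consensus curation.

All coordinates in files are 1-based; in memory every position and column
index is 0-based. The conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .alphabet import can_pair
from .errors import StructureFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import Alignment, ColumnMap

# Bracket alphabets recognized in WUSS / extended dot-bracket strings.
_OPEN = "(<[{"
_CLOSE = ")>]}"
_MATCH = dict(zip(_CLOSE, _OPEN))
# Unpaired/loop annotation characters in WUSS.
_UNPAIRED = set(".,:_-~")

PROV_KEPT = "consensus-kept"
PROV_REMOVED = "removed-incompatible"
PROV_EXTENSION = "helix-extension"


def crosses(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True if base pairs *p* and *q* cross (pseudoknot relation)."""
    (i, j), (k, l) = sorted((tuple(sorted(p)), tuple(sorted(q))))
    return i < k < j < l


def is_nested(pairs: Iterable[tuple[int, int]]) -> bool:
    ps = [tuple(sorted(p)) for p in pairs]
    return not any(crosses(p, q) for a, p in enumerate(ps) for q in ps[a + 1:])


def parse_wuss(ss: str) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Parse a WUSS/extended dot-bracket string into base pairs (0-based).

    Each bracket family ``()``, ``<>``, ``[]``, ``{}`` is matched with its own
    stack; ``Aa``/``Bb``... pseudoknot letters are matched uppercase-opening /
    lowercase-closing. Letter pairs always go to the crossing list. Bracket
    pairs are split into a maximal nested set (greedy, left-to-right) and a
    crossing remainder, so e.g. ``((..[.))..]`` yields a nested helix plus one
    crossing pair.
    """
    stacks: dict[str, list[int]] = {}
    bracket_pairs: list[tuple[int, int]] = []
    letter_pairs: list[tuple[int, int]] = []
    for col, c in enumerate(ss):
        if c in _OPEN:
            stacks.setdefault(c, []).append(col)
        elif c in _CLOSE:
            stack = stacks.get(_MATCH[c], [])
            if not stack:
                raise StructureFormatError(
                    f"unmatched '{c}' at column {col + 1} in structure line")
            bracket_pairs.append((stack.pop(), col))
        elif c.isalpha() and c.isupper():
            stacks.setdefault(c, []).append(col)
        elif c.isalpha() and c.islower():
            stack = stacks.get(c.upper(), [])
            if not stack:
                raise StructureFormatError(
                    f"unmatched pseudoknot letter '{c}' at column {col + 1}")
            letter_pairs.append((stack.pop(), col))
        elif c in _UNPAIRED:
            continue
        else:
            raise StructureFormatError(f"unrecognized structure character {c!r}")
    leftovers = [c for c, s in stacks.items() if s]
    if leftovers:
        raise StructureFormatError(f"unclosed bracket(s) {leftovers} in structure line")

    nested: list[tuple[int, int]] = []
    crossing: list[tuple[int, int]] = list(letter_pairs)
    for p in sorted(bracket_pairs):
        if any(crosses(p, q) for q in nested):
            crossing.append(p)
        else:
            nested.append(p)
    return sorted(nested), sorted(crossing)


@dataclass
class CuratedStructure:
    """A set of base pairs on a target sequence with per-pair provenance.

    Invariants (enforced by :meth:`validate`): pairs are mutually exclusive
    (each position in at most one pair) and nested; when a sequence is
    attached every pair is Watson-Crick or wobble on it.
    """

    base_pairs: list[tuple[int, int]]
    provenance: dict[tuple[int, int], str] = field(default_factory=dict)
    sequence: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        self.base_pairs = sorted(tuple(sorted(p)) for p in self.base_pairs)
        if self.n is None and self.sequence is not None:
            self.n = len(self.sequence)

    @property
    def pair_set(self) -> set[tuple[int, int]]:
        return set(self.base_pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.base_pairs:
            d[i] = j
            d[j] = i
        return d

    def validate(self, check_pairing: bool = True) -> None:
        """Check exclusivity, range and nesting; with ``check_pairing`` also
        WC/wobble compatibility on the attached sequence (curation output
        guarantees it; reference structures read from files need not)."""
        seen: set[int] = set()
        for i, j in self.base_pairs:
            if i == j:
                raise StructureFormatError(f"self-pair at position {i + 1}")
            if i in seen or j in seen:
                raise StructureFormatError(
                    f"position in more than one pair near ({i + 1},{j + 1})")
            seen.update((i, j))
            if self.n is not None and not (0 <= i < self.n and 0 <= j < self.n):
                raise StructureFormatError(f"pair ({i + 1},{j + 1}) out of range 1..{self.n}")
            if check_pairing and self.sequence is not None \
                    and not can_pair(self.sequence[i], self.sequence[j]):
                raise StructureFormatError(
                    f"pair ({i + 1},{j + 1}) is not WC/wobble on the sequence")
        if not is_nested(self.base_pairs):
            raise StructureFormatError("base pairs are not nested")


def pairs_to_dotbracket(pairs: Iterable[tuple[int, int]], n: int) -> str:
    s = ["."] * n
    for i, j in pairs:
        i, j = sorted((i, j))
        s[i], s[j] = "(", ")"
    return "".join(s)


def dotbracket_to_pairs(s: str) -> list[tuple[int, int]]:
    nested, crossing = parse_wuss(s)
    if crossing:
        raise StructureFormatError("dot-bracket string contains crossing pairs")
    return nested


# ---------------------------------------------------------------------------
# File I/O: dot-bracket and CT
# ---------------------------------------------------------------------------

def _noncomment_lines(text: str) -> list[str]:
    return [ln.rstrip("\n") for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]


def read_secondary_structure(path: str | Path, format: str | None = None) -> CuratedStructure:
    """Read a dot-bracket or CT file into a :class:`CuratedStructure`.

    Dot-bracket files: an optional ``>name`` header, an optional sequence
    line, and the structure line. CT files use the standard six-column layout
    with 1-based numbering and 0 meaning unpaired.
    """
    path = Path(path)
    if format is None:
        format = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
    text = path.read_text()
    if format == "dotbracket":
        return _read_dotbracket(text)
    if format == "ct":
        return _read_ct(text)
    raise StructureFormatError(f"unknown secondary-structure format {format!r}")


def _read_dotbracket(text: str) -> CuratedStructure:
    lines = _noncomment_lines(text)
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if not lines:
        raise StructureFormatError("empty dot-bracket file")
    seq: str | None = None
    if len(lines) >= 2:
        seq, struct = lines[0], lines[1]
        if len(seq) != len(struct):
            raise StructureFormatError("sequence and structure lines differ in length")
    else:
        struct = lines[0]
    cs = CuratedStructure(dotbracket_to_pairs(struct), sequence=seq, n=len(struct))
    cs.validate(check_pairing=False)
    return cs


def _read_ct(text: str) -> CuratedStructure:
    lines = _noncomment_lines(text)
    if not lines:
        raise StructureFormatError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError("malformed CT header line") from exc
    if len(lines) - 1 < n:
        raise StructureFormatError(f"CT file declares {n} rows, found {len(lines) - 1}")
    seq = []
    partner = [0] * n
    for ln in lines[1:n + 1]:
        fields = ln.split()
        if len(fields) < 6:
            raise StructureFormatError(f"short CT row: {ln!r}")
        idx, base, pair = int(fields[0]), fields[1], int(fields[4])
        if not (1 <= idx <= n) or not (0 <= pair <= n):
            raise StructureFormatError(f"CT position out of range in row {ln!r}")
        seq.append(base)
        partner[idx - 1] = pair
    pairs = []
    for i0, p in enumerate(partner):
        if p == 0:
            continue
        if partner[p - 1] != i0 + 1:
            raise StructureFormatError(
                f"conflicting pair assignment between rows {i0 + 1} and {p}")
        if p - 1 > i0:
            pairs.append((i0, p - 1))
    cs = CuratedStructure(pairs, sequence="".join(seq), n=n)
    cs.validate(check_pairing=False)
    return cs


def write_secondary_structure(struct: CuratedStructure, path: str | Path,
                              format: str | None = None, name: str = "structure",
                              header: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
    n = struct.n if struct.n is not None else (
        max((j for _, j in struct.base_pairs), default=-1) + 1)
    seq = struct.sequence or "N" * n
    out = [] if header is None else [f"# {header}"]
    if format == "dotbracket":
        out += [f">{name}", seq, pairs_to_dotbracket(struct.base_pairs, n)]
    elif format == "ct":
        partner = [0] * n
        for i, j in struct.base_pairs:
            partner[i], partner[j] = j + 1, i + 1
        out.append(f"{n} {name}")
        for i in range(n):
            out.append(f"{i + 1} {seq[i]} {i} {i + 2 if i + 1 < n else 0} {partner[i]} {i + 1}")
    else:
        raise StructureFormatError(f"unknown secondary-structure format {format!r}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Consensus curation
# ---------------------------------------------------------------------------

def curate_consensus(aln: "Alignment", cmap: "ColumnMap", extend_helices: bool = False,
                     min_loop: int = 3) -> CuratedStructure:
    """Curate the alignment's consensus structure for a specific target.

    Each consensus column pair is mapped onto target positions; pairs whose
    ends fall on gaps of the target row, or whose target nucleotides are not
    Watson-Crick/wobble-compatible, are removed. With ``extend_helices`` kept
    helices are grown outward/inward by pairs ``(i-1, j+1)`` / ``(i+1, j-1)``
    whenever the added pair is compatible, conflict-free, nested with the kept
    set and leaves at least ``min_loop`` unpaired nucleotides in a hairpin.
    """
    if aln.consensus_structure is None:
        raise StructureFormatError("alignment has no consensus structure to curate")
    target = cmap.target_sequence
    kept: list[tuple[int, int]] = []
    prov: dict[tuple[int, int], str] = {}
    for ci, cj in aln.consensus_structure:
        pi, pj = cmap.col_to_pos[ci], cmap.col_to_pos[cj]
        if pi < 0 or pj < 0 or not can_pair(target[pi], target[pj]):
            key = (min(ci, cj), max(ci, cj))
            prov[key] = PROV_REMOVED
            continue
        i, j = sorted((int(pi), int(pj)))
        kept.append((i, j))
        prov[(i, j)] = PROV_KEPT

    if extend_helices:
        occupied = {p for pair in kept for p in pair}
        all_pairs = list(kept)
        changed = True
        while changed:
            changed = False
            for i, j in sorted(all_pairs):
                for a, b in ((i - 1, j + 1), (i + 1, j - 1)):
                    if not (0 <= a < b < len(target)):
                        continue
                    if a in occupied or b in occupied:
                        continue
                    if b - a - 1 < min_loop:
                        continue
                    if not can_pair(target[a], target[b]):
                        continue
                    if any(crosses((a, b), q) for q in all_pairs):
                        continue
                    all_pairs.append((a, b))
                    prov[(a, b)] = PROV_EXTENSION
                    occupied.update((a, b))
                    changed = True
        kept = all_pairs

    cs = CuratedStructure(sorted(kept), provenance=prov, sequence=target)
    cs.validate()
    return cs


def restrict_pairs(pairs: Sequence[tuple[int, int]],
                   assessable: set[int]) -> set[tuple[int, int]]:
    """Keep only pairs with both ends in *assessable*."""
    return {tuple(sorted(p)) for p in pairs
            if p[0] in assessable and p[1] in assessable}
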