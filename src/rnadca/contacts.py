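"""Tertiary-contact ranking, enrichment statistics and restraint export.

Candidate nucleotide pairs are ranked by a coevolution score after removing
trivially proximal pairs: all (i, j) with |i - j| < 5, and for every
secondary-structure base pair (k, l) the 25 pairs (k +/- {0,1,2},
l +/- {0,1,2}). A pair is a true positive when the minimal heavy-atom
distance between the two residues in a reference structure is below a 4 or
8 Angstrom threshold. Contact enrichment along the ranked list is assessed
with a sliding window of Y = 10% of the list: the number T of true positives
in ranks X+1..X+Y is compared with an exact binomial null whose success rate
r0 is the true-positive fraction among all pairs of rank > X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .alignment import ColumnMap
from .coevolution import ScoreMatrix
from .errors import MappingError, ParameterError, RnaDcaError
from .structures import CuratedStructure

_NUCLEOTIDES = {"A", "C", "G", "U"}

REASON_NEAR_DIAGONAL = "near-diagonal"
REASON_SS_NEIGHBORHOOD = "ss-neighborhood"
REASON_UNMAPPABLE = "unmappable"


@dataclass
class ContactMap:
    """Minimal heavy-atom distances between residues of one chain."""

    n: int
    dist: np.ndarray            # (n, n), Angstrom; NaN where unresolved
    resolved: set[int]          # residues with at least one heavy atom
    sequence: str               # one-letter chain sequence
    index_table: list[tuple[int, str]]  # sequential index -> (PDB resseq, icode)


@dataclass
class RankedPair:
    i: int          # target positions, i < j
    j: int
    score: float
    dist: float     # NaN if no contact map supplied
    is_tp: bool


@dataclass
class RankedPairList:
    pairs: list[RankedPair]
    excluded: dict[str, list[tuple[int, int]]]
    threshold: float | None
    target_sequence: str

    def tp_labels(self) -> np.ndarray:
        return np.array([p.is_tp for p in self.pairs], dtype=bool)


@dataclass
class EnrichmentScan:
    window: int
    offsets: np.ndarray      # X values
    t_counts: np.ndarray     # T(X, Y)
    r0: np.ndarray
    pvalues: np.ndarray
    alpha: float
    first_crossing: int
    sensitivity: float
    precision: float
    no_predictions: bool = False


# ---------------------------------------------------------------------------
# Contact maps from PDB
# ---------------------------------------------------------------------------

def contact_map_from_pdb(path: str | Path, chain: str) -> ContactMap:
    """Minimal non-hydrogen inter-residue distances of one chain.

    Standard RNA residues (A, C, G, U) only; waters, ions and heteroatoms
    are skipped; disordered atoms contribute their highest-occupancy
    conformer (Bio.PDB's default selection). Residues are indexed by their
    sequential position along the chain; the PDB numbering (with insertion
    codes) is kept in ``index_table``.
    """
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    if chain not in [c.id for c in model]:
        raise MappingError(f"chain {chain!r} not present in {path}")
    coords: list[np.ndarray] = []
    seq: list[str] = []
    table: list[tuple[int, str]] = []
    for res in model[chain]:
        het, resseq, icode = res.id
        name = res.get_resname().strip()
        if het != " " or name not in _NUCLEOTIDES:
            continue
        heavy = np.array([a.get_coord() for a in res.get_atoms()
                          if a.element not in ("H", "D")], dtype=np.float64)
        seq.append(name)
        table.append((resseq, icode.strip()))
        coords.append(heavy)
    if not seq:
        raise MappingError(f"chain {chain!r} contains no standard nucleotides")
    n = len(seq)
    dist = np.full((n, n), np.nan)
    resolved = {i for i, c in enumerate(coords) if len(c)}
    for i in sorted(resolved):
        dist[i, i] = 0.0
        for j in sorted(resolved):
            if j <= i:
                continue
            d = np.sqrt(((coords[i][:, None, :] - coords[j][None, :, :]) ** 2
                         ).sum(axis=2)).min()
            dist[i, j] = dist[j, i] = float(d)
    return ContactMap(n=n, dist=dist, resolved=resolved,
                      sequence="".join(seq), index_table=table)


def map_chain_to_target(cm: ContactMap, target_sequence: str) -> int:
    """Offset such that chain residue r sits at target position r + offset.

    Reconciliation is by exact substring match of the chain sequence in the
    ungapped target (or vice versa with a negative offset).
    """
    pos = target_sequence.find(cm.sequence)
    if pos >= 0:
        return pos
    pos = cm.sequence.find(target_sequence)
    if pos >= 0:
        return -pos
    raise MappingError(
        "chain sequence does not match the target sequence: "
        f"chain={cm.sequence[:40]}... target={target_sequence[:40]}...")


# ---------------------------------------------------------------------------
# Filtering and ranking
# ---------------------------------------------------------------------------

def _near_ss(i: int, j: int, ss_pairs: list[tuple[int, int]], radius: int) -> bool:
    for k, l in ss_pairs:
        if (abs(i - k) <= radius and abs(j - l) <= radius) or \
           (abs(i - l) <= radius and abs(j - k) <= radius):
            return True
    return False


def filter_and_rank(scores: ScoreMatrix, cmap: ColumnMap, ss: CuratedStructure,
                    cm: ContactMap | None = None, threshold_A: float = 8.0,
                    min_separation: int = 5, ss_radius: int = 2,
                    chain_offset: int = 0) -> RankedPairList:
    """Rank candidate tertiary pairs by score after the two exclusion rules.

    Every column pair is mapped onto target positions. Pairs are excluded,
    with exactly one recorded reason each (first matching rule), when they
    cannot be mapped or are unresolved in the contact map (``unmappable``),
    when |i - j| < ``min_separation`` (``near-diagonal``), or when they fall
    within +/- ``ss_radius`` of a secondary-structure base pair
    (``ss-neighborhood``). Without a contact map all pairs are labelled
    FP and distances are NaN (blind prediction).
    """
    ss_pairs = [tuple(sorted(p)) for p in ss.base_pairs]
    retained: list[RankedPair] = []
    excluded: dict[str, list[tuple[int, int]]] = {
        REASON_UNMAPPABLE: [], REASON_NEAR_DIAGONAL: [], REASON_SS_NEIGHBORHOOD: []}
    for ci, cj, val in scores.ranked_pairs():
        pi, pj = int(cmap.col_to_pos[ci]), int(cmap.col_to_pos[cj])
        if pi < 0 or pj < 0:
            excluded[REASON_UNMAPPABLE].append((ci, cj))
            continue
        i, j = sorted((pi, pj))
        if cm is not None:
            ri, rj = i - chain_offset, j - chain_offset
            in_map = (0 <= ri < cm.n and 0 <= rj < cm.n
                      and ri in cm.resolved and rj in cm.resolved)
        else:
            in_map = True
        if not in_map:
            excluded[REASON_UNMAPPABLE].append((i, j))
            continue
        if abs(i - j) < min_separation:
            excluded[REASON_NEAR_DIAGONAL].append((i, j))
            continue
        if _near_ss(i, j, ss_pairs, ss_radius):
            excluded[REASON_SS_NEIGHBORHOOD].append((i, j))
            continue
        if cm is not None:
            d = float(cm.dist[i - chain_offset, j - chain_offset])
            retained.append(RankedPair(i, j, val, d, d <= threshold_A))
        else:
            retained.append(RankedPair(i, j, val, float("nan"), False))
    return RankedPairList(pairs=retained, excluded=excluded,
                          threshold=threshold_A if cm is not None else None,
                          target_sequence=cmap.target_sequence)


def tp_rate_curve(rpl: RankedPairList) -> dict[str, np.ndarray]:
    """Cumulative precision vs. number of predictions, plus the distance-ranked
    oracle curve (the theoretical best ordering of the same pairs)."""
    if not rpl.pairs:
        raise ParameterError("ranked pair list is empty")
    labels = rpl.tp_labels().astype(float)
    k = np.arange(1, labels.size + 1)
    precision = np.cumsum(labels) / k
    dists = np.array([p.dist for p in rpl.pairs])
    oracle_labels = labels[np.argsort(dists, kind="stable")]
    oracle = np.cumsum(oracle_labels) / k
    return {"n_predictions": k, "precision": precision, "oracle_precision": oracle}


# ---------------------------------------------------------------------------
# Sliding-window binomial enrichment
# ---------------------------------------------------------------------------

def binomial_tail(t: int, y: int, r0: float) -> float:
    """Exact P[Binomial(y, r0) >= t] by direct summation of PMF terms."""
    if t <= 0:
        return 1.0
    if t > y:
        return 0.0
    if r0 <= 0.0:
        return 0.0
    if r0 >= 1.0:
        return 1.0
    return float(sum(math.comb(y, k) * r0 ** k * (1.0 - r0) ** (y - k)
                     for k in range(t, y + 1)))


def enrichment_scan(rpl: RankedPairList, window_fraction: float = 0.10,
                    alpha: float = 0.01) -> EnrichmentScan:
    """Sliding-window contact enrichment along the ranked pair list.

    Window size Y is ``window_fraction`` of the list, rounded half-up and
    floored at 1. For each offset X the null success rate r0(X) is the TP
    fraction among all pairs of rank > X (already-predicted contacts cannot
    be predicted again); p(X) is the exact binomial tail probability of
    observing at least T(X, Y) true positives in Y i.i.d. draws.
    ``first_crossing`` is the smallest X with p(X) > alpha (or one past the
    last scanned offset if the whole list stays enriched), and sensitivity /
    precision of the first X predictions are reported at that point.
    """
    labels = rpl.tp_labels()
    total = labels.size
    if total == 0:
        raise ParameterError("ranked pair list is empty")
    Y = max(1, math.floor(window_fraction * total + 0.5))
    if Y > total:
        raise ParameterError("window exceeds list length")
    offsets, tcounts, r0s, ps = [], [], [], []
    cum = np.concatenate([[0], np.cumsum(labels)])
    total_tp = int(cum[-1])
    for X in range(0, total - Y + 1):
        T = int(cum[X + Y] - cum[X])
        rem = total - X
        r0 = (total_tp - int(cum[X])) / rem
        offsets.append(X)
        tcounts.append(T)
        r0s.append(r0)
        ps.append(binomial_tail(T, Y, r0))
    ps_arr = np.array(ps)
    above = np.nonzero(ps_arr > alpha)[0]
    first = int(offsets[above[0]]) if above.size else offsets[-1] + 1
    tp_at = int(cum[first])
    sens = tp_at / total_tp if total_tp else 1.0
    prec = tp_at / first if first else 1.0
    return EnrichmentScan(window=Y, offsets=np.array(offsets),
                          t_counts=np.array(tcounts), r0=np.array(r0s),
                          pvalues=ps_arr, alpha=alpha, first_crossing=first,
                          sensitivity=sens, precision=prec,
                          no_predictions=(first == 0))


# ---------------------------------------------------------------------------
# Restraint export
# ---------------------------------------------------------------------------

#: One representative base atom per nucleotide: the Watson-Crick edge
#: nitrogen (N1 of purines, N3 of pyrimidines). Configurable placeholder;
#: finer atom-pair tables can be passed to export_restraints.
DEFAULT_ATOM_RULE = {"A": "N1", "G": "N1", "C": "N3", "U": "N3"}


def format_restraints(rpl: RankedPairList, top_n: int,
                      atom_rule: dict[str, str] | None = None,
                      upper_A: float = 8.0) -> tuple[str, str]:
    """Render the top-n ranked pairs as restraint text (TSV and Rosetta).

    Rosetta lines are flat-bottom ``AtomPair`` constraints with zero penalty
    up to ``upper_A`` (soft homogeneous distance constraints; native
    distances are unknown). Residue numbers are 1-based.
    """
    if top_n < 0:
        raise ParameterError(f"top_n must be non-negative, got {top_n}")
    if top_n > len(rpl.pairs):
        raise ParameterError(
            f"top_n={top_n} exceeds ranked list length {len(rpl.pairs)}")
    rule = DEFAULT_ATOM_RULE if atom_rule is None else atom_rule
    seq = rpl.target_sequence
    tsv = ["i\tj\tatom_i\tatom_j\tscore\tupper_A"]
    rosetta = []
    for p in rpl.pairs[:top_n]:
        ai, aj = rule[seq[p.i]], rule[seq[p.j]]
        tsv.append(f"{p.i + 1}\t{p.j + 1}\t{ai}\t{aj}\t{p.score:.6g}\t{upper_A:g}")
        rosetta.append(
            f"AtomPair {ai} {p.i + 1} {aj} {p.j + 1} FLAT_HARMONIC 0.0 1.0 {upper_A:g}")
    return "\n".join(tsv) + "\n", "\n".join(rosetta) + ("\n" if rosetta else "")


def write_restraints(rpl: RankedPairList, top_n: int, tsv_path: str | Path,
                     rosetta_path: str | Path, atom_rule: dict[str, str] | None = None,
                     upper_A: float = 8.0, header: str | None = None) -> None:
    tsv, ros = format_restraints(rpl, top_n, atom_rule=atom_rule, upper_A=upper_A)
    prefix = f"# {header}\n" if header else ""
    Path(tsv_path).write_text(prefix + tsv)
    Path(rosetta_path).write_text(prefix + ros)


def read_restraints(path: str | Path) -> list[tuple[str, int, str, int, float]]:
    """Parse either restraint flavour back into (atom_i, i, atom_j, j, upper)."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.startswith("i\t"):
            continue
        f = ln.split()
        if f[0] == "AtomPair":
            out.append((f[1], int(f[2]) - 1, f[3], int(f[4]) - 1, float(f[8])))
        else:
            try:
                out.append((f[2], int(f[0]) - 1, f[3], int(f[1]) - 1, float(f[5])))
            except (ValueError, IndexError) as exc:
                raise RnaDcaError(f"unparseable restraint line {ln!r}") from exc
    return out
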