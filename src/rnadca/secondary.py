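"""Covariation-guided secondary structure prediction (generalized Nussinov).

The pair-scoring matrix for a target sequence is prefilled with -1 for
nucleotide pairs that cannot form a Watson-Crick or wobble pair and 0 for
compatible ones; then the L largest covariation scores (L = alignment
length) are mapped onto target positions and written into compatible,
mappable cells. A Nussinov-style dynamic program maximizes the total pair
score over nested structures with a minimum hairpin loop of three unpaired
nucleotides; only strictly positive cells can be paired, which prevents the
overpairing a raw-MI score matrix would cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import ColumnMap
from .alphabet import can_pair
from .coevolution import ScoreMatrix
from .errors import ParameterError
from .structures import CuratedStructure, restrict_pairs

PREFILL_INCOMPATIBLE = 0
PREFILL_COMPATIBLE = 1
COVARIANCE = 2


@dataclass
class PairScoreMatrix:
    """Per-target-position pair scores: -1, 0 or a positive covariation score."""

    n: int
    scores: np.ndarray      # (n, n) symmetric; diagonal unused
    provenance: np.ndarray  # (n, n) int8 codes, see module constants


@dataclass
class SecondaryStructure:
    """A nested set of base pairs on a target with the DP total score."""

    pairs: set[tuple[int, int]]
    score: float
    n: int


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    no_predictions: bool = False
    excluded_positions: set[int] = field(default_factory=set)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def precision(self) -> float:
        # 0/0 reported as 1.0; no_predictions flags the degenerate case
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0


def build_pair_scores(scores: ScoreMatrix, cmap: ColumnMap,
                      top_k: int | None = None) -> PairScoreMatrix:
    """Construct the masked pair-scoring matrix for the target sequence.

    ``top_k`` defaults to the alignment length L, capping the number of
    retained covariation scores; candidate scores that fall on gap columns of
    the target row or on incompatible nucleotides leave the prefill in place.
    """
    if top_k is None:
        top_k = scores.L
    if top_k < 0:
        raise ParameterError(f"top_k must be non-negative, got {top_k}")
    target = cmap.target_sequence
    n = len(target)
    s = np.zeros((n, n))
    prov = np.full((n, n), PREFILL_COMPATIBLE, dtype=np.int8)
    for i in range(n):
        for j in range(n):
            if i != j and not can_pair(target[i], target[j]):
                s[i, j] = -1.0
                prov[i, j] = PREFILL_INCOMPATIBLE

    for ci, cj, val in scores.ranked_pairs()[:top_k]:
        pi, pj = int(cmap.col_to_pos[ci]), int(cmap.col_to_pos[cj])
        if pi < 0 or pj < 0:
            continue
        if not can_pair(target[pi], target[pj]):
            continue
        s[pi, pj] = s[pj, pi] = val
        prov[pi, pj] = prov[pj, pi] = COVARIANCE
    return PairScoreMatrix(n=n, scores=s, provenance=prov)


def nussinov(psm: PairScoreMatrix, min_loop: int = 3) -> SecondaryStructure:
    """Maximum-score nested structure by dynamic programming with traceback.

    A pair (i, j) is allowed only if its cell score is strictly positive and
    j - i - 1 >= ``min_loop``. Traceback is deterministic with precedence
    pair > bifurcation (smallest split) > leave i unpaired > leave j
    unpaired.
    """
    n, s = psm.n, psm.scores
    N = np.zeros((n + 1, n + 1))  # N[i, j] over closed interval i..j, j < i => 0

    def pairable(i: int, j: int) -> bool:
        return s[i, j] > 0.0 and j - i - 1 >= min_loop

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = max(N[i + 1, j], N[i, j - 1])
            if pairable(i, j):
                best = max(best, N[i + 1, j - 1] + s[i, j])
            for k in range(i + 1, j - 1):
                v = N[i, k] + N[k + 1, j]
                if v > best:
                    best = v
            N[i, j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)] if n > 1 else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        v = N[i, j]
        if pairable(i, j) and np.isclose(v, N[i + 1, j - 1] + s[i, j]):
            pairs.add((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j - 1):
            if np.isclose(v, N[i, k] + N[k + 1, j]) and N[i, k] > 0 and N[k + 1, j] > 0:
                stack.extend([(i, k), (k + 1, j)])
                break
        else:
            if np.isclose(v, N[i + 1, j]):
                stack.append((i + 1, j))
            else:
                stack.append((i, j - 1))
    return SecondaryStructure(pairs=pairs, score=float(N[0, n - 1]) if n > 1 else 0.0,
                              n=n)


def evaluate_structure(pred: SecondaryStructure, ref: CuratedStructure,
                       assessable: set[int] | None = None) -> EvaluationReport:
    """Compare predicted and reference pairs on the assessable positions.

    Both pair sets are restricted to pairs with both ends in ``assessable``
    (default: every target position); TP/FP/FN follow by set arithmetic.
    """
    all_pos = set(range(pred.n))
    assessable = all_pos if assessable is None else set(assessable)
    p = restrict_pairs(sorted(pred.pairs), assessable)
    r = restrict_pairs(ref.base_pairs, assessable)
    return EvaluationReport(
        tp=len(p & r), fp=len(p - r), fn=len(r - p),
        no_predictions=(len(p) == 0),
        excluded_positions=all_pos - assessable,
    )


def topk_sweep(scores: ScoreMatrix, cmap: ColumnMap, ref: CuratedStructure,
               ks: list[int], min_loop: int = 3,
               assessable: set[int] | None = None) -> list[dict]:
    """Sensitivity/precision of the fold as a function of the top-k cutoff."""
    out = []
    for k in ks:
        psm = build_pair_scores(scores, cmap, top_k=k)
        rep = evaluate_structure(nussinov(psm, min_loop=min_loop), ref, assessable)
        out.append({"top_k": k, "tp": rep.tp, "fp": rep.fp, "fn": rep.fn,
                    "sensitivity": rep.sensitivity, "precision": rep.precision})
    return out
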