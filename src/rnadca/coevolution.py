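"""Coevolution scores on RNA alignments: mean-field DCA, MI and MIapc.

The alignment is modelled as a 5-state Potts model

    P(A_1..A_L) = exp( sum_{i<j} e_ij(A_i, A_j) + sum_i h_i(A_i) ) / Z ,

whose couplings e_ij are inferred by the mean-field approximation: the
(q-1)L x (q-1)L connected-correlation matrix of the reweighted, pseudocounted
single- and pair-column frequencies is inverted, and e_ij is (minus) the
corresponding off-diagonal block, gauge-fixed to zero row/column sums. Pair
scores are the Frobenius norms of the coupling blocks with the average
product correction (Fapc). Mutual information, with and without the same
correction, serves as the local-covariation baseline.

Sequences are reweighted by 1/(number of >= 90%-identical neighbours,
including self), so that Meff = sum of weights is the effective sequence
number of the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Q
from .alignment import Alignment
from .errors import NumericalError, ParameterError

#: Index of the mean-field reference state (the gap) in the fixed
#: alphabet order (-, A, C, G, U).
REFERENCE_STATE = 0


@dataclass
class SequenceWeights:
    weights: np.ndarray          # (M,), each in (0, 1]
    identity_threshold: float

    @property
    def Meff(self) -> float:
        return float(self.weights.sum())


@dataclass
class FrequencyModel:
    """Reweighted, pseudocounted column marginals.

    ``fi`` has shape (L, q); ``fij`` shape (L, L, q, q) with
    ``fij[i, j] == fij[j, i].T`` and undefined (zero) diagonal blocks.
    """

    fi: np.ndarray
    fij: np.ndarray
    pseudocount_weight: float
    Meff: float

    @property
    def L(self) -> int:
        return self.fi.shape[0]

    @property
    def q(self) -> int:
        return self.fi.shape[1]


@dataclass
class CouplingModel:
    """Zero-sum-gauge couplings ``eij[(i, j)]`` (L, L, q, q) and fields (L, q)."""

    eij: np.ndarray
    hi: np.ndarray
    gauge: str = "zero-sum"

    @property
    def L(self) -> int:
        return self.hi.shape[0]


@dataclass
class ScoreMatrix:
    """Symmetric per-column-pair scores with an undefined (NaN) diagonal."""

    scores: np.ndarray
    kind: str  # MI | MIapc | Fapc

    @property
    def L(self) -> int:
        return self.scores.shape[0]

    def ranked_pairs(self) -> list[tuple[int, int, float]]:
        """All column pairs i<j, sorted by descending score (ties by index)."""
        L = self.L
        iu, ju = np.triu_indices(L, k=1)
        vals = self.scores[iu, ju]
        order = np.lexsort((ju, iu, -vals))
        return [(int(iu[k]), int(ju[k]), float(vals[k])) for k in order]


# ---------------------------------------------------------------------------
# Reweighting
# ---------------------------------------------------------------------------

def compute_weights(aln: Alignment, threshold: float = 0.9,
                    chunk: int = 256) -> SequenceWeights:
    """Down-weight redundant sequences.

    The identity of two rows is the fraction of columns with equal characters
    (gap-gap counts as a match). Each sequence gets weight 1/n where n is the
    number of rows (itself included) at identity >= ``threshold``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"identity threshold must be in (0, 1], got {threshold}")
    X = aln.matrix
    M, L = X.shape
    counts = np.zeros(M, dtype=np.int64)
    cut = threshold * L - 1e-9  # tolerate float round-off at exact threshold
    for start in range(0, M, chunk):
        block = X[start:start + chunk]
        matches = (block[:, None, :] == X[None, :, :]).sum(axis=2)
        counts[start:start + chunk] += (matches >= cut).sum(axis=1)
        # counted per block row over all M, accumulate into the block rows
    weights = 1.0 / counts
    return SequenceWeights(weights=weights, identity_threshold=threshold)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def compute_frequencies(aln: Alignment, weights: SequenceWeights | None = None,
                        pseudocount_weight: float = 0.5) -> FrequencyModel:
    """Reweighted empirical marginals mixed with the uniform distribution.

    ``fi = (1 - lam) * f_data + lam / q`` and
    ``fij = (1 - lam) * f_data + lam / q**2`` for i != j, which keeps the
    marginalization of ``fij`` over one index exactly consistent with ``fi``.
    """
    lam = pseudocount_weight
    if not (0.0 <= lam <= 1.0):
        raise ParameterError(f"pseudocount weight must be in [0, 1], got {lam}")
    X = aln.matrix
    M, L = X.shape
    w = np.ones(M) if weights is None else np.asarray(weights.weights, dtype=float)
    if w.shape != (M,):
        raise ParameterError("weights length does not match alignment depth")
    meff = float(w.sum())

    onehot = np.zeros((M, L, Q))
    onehot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    fi_data = np.einsum("m,mia->ia", w, onehot) / meff
    wh = onehot * w[:, None, None]
    fij_data = np.einsum("mia,mjb->ijab", wh, onehot) / meff

    fi = (1.0 - lam) * fi_data + lam / Q
    fij = (1.0 - lam) * fij_data + lam / Q**2
    idx = np.arange(L)
    fij[idx, idx] = 0.0  # diagonal blocks are not part of the model
    return FrequencyModel(fi=fi, fij=fij, pseudocount_weight=lam, Meff=meff)


# ---------------------------------------------------------------------------
# Mean-field inversion
# ---------------------------------------------------------------------------

def mean_field_couplings(freq: FrequencyModel) -> CouplingModel:
    """Infer Potts couplings by naive mean field (inverse covariance).

    The connected-correlation matrix C over the q-1 non-reference states of
    every column is inverted with a direct dense solve; couplings are
    ``-C^{-1}`` blocks, zero-padded on the reference (gap) state and shifted
    to the zero-sum gauge. Fields follow from the mean-field self-consistency
    ``h_i(A) = log f_i(A)/f_i(ref) - sum_j e_ij(A, .) f_j``.
    """
    if freq.pseudocount_weight <= 0.0:
        raise ParameterError("mean-field inversion requires a positive pseudocount")
    L, q = freq.L, freq.q
    qr = q - 1  # non-reference states 1..q-1
    fi = freq.fi
    fij = freq.fij

    C = np.empty((L, qr, L, qr))
    # off-diagonal blocks: connected pair correlations
    C[:] = (fij[:, :, 1:, 1:] - fi[:, None, 1:, None] * fi[None, :, None, 1:]
            ).transpose(0, 2, 1, 3)
    # diagonal blocks: single-column covariance
    idx = np.arange(L)
    diag = (np.einsum("ia,ab->iab", fi[:, 1:], np.eye(qr))
            - fi[:, 1:, None] * fi[:, None, 1:])
    C[idx, :, idx, :] = diag
    Cm = C.reshape(L * qr, L * qr)
    Cm = 0.5 * (Cm + Cm.T)
    try:
        Cinv = np.linalg.inv(Cm)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "connected-correlation matrix is singular; "
            "raise the pseudocount weight") from exc

    e = np.zeros((L, L, q, q))
    blocks = -Cinv.reshape(L, qr, L, qr).transpose(0, 2, 1, 3)
    e[:, :, 1:, 1:] = blocks
    e[idx, idx] = 0.0
    # zero-sum gauge: subtract row/column means, add back the grand mean
    row = e.mean(axis=3, keepdims=True)
    col = e.mean(axis=2, keepdims=True)
    tot = e.mean(axis=(2, 3), keepdims=True)
    e = e - row - col + tot
    e[idx, idx] = 0.0

    with np.errstate(divide="ignore"):
        hi = np.log(fi) - np.log(fi[:, REFERENCE_STATE])[:, None]
    hi -= np.einsum("ijab,jb->ia", e, fi)
    return CouplingModel(eij=e, hi=hi)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _apc(F: np.ndarray) -> np.ndarray:
    """Average product correction with off-diagonal means (diagonal excluded)."""
    L = F.shape[0]
    if L < 2:
        return np.zeros_like(F)
    off = ~np.eye(L, dtype=bool)
    col_mean = np.where(off, F, 0.0).sum(axis=1) / (L - 1)
    grand = np.where(off, F, 0.0).sum() / (L * (L - 1))
    if grand == 0.0:
        return np.zeros_like(F)
    return np.outer(col_mean, col_mean) / grand


def frobenius_apc_score(couplings: CouplingModel, include_gap: bool = True) -> ScoreMatrix:
    """Compress coupling matrices to the Fapc scalar score.

    F(i,j) is the Frobenius norm of the zero-sum-gauge e_ij (over all five
    states by default; ``include_gap=False`` drops the gap row/column), and
    Fapc(i,j) = F(i,j) - F(i,.) F(.,j) / F(.,.).
    """
    e = couplings.eij if include_gap else couplings.eij[:, :, 1:, 1:]
    F = np.sqrt((e ** 2).sum(axis=(2, 3)))
    scores = F - _apc(F)
    np.fill_diagonal(scores, np.nan)
    return ScoreMatrix(scores=scores, kind="Fapc")


def mutual_information(freq: FrequencyModel, apc: bool = False) -> ScoreMatrix:
    """Mutual information between column pairs (natural log, nats).

    ``M_ij = sum_{A,B} f_ij(A,B) log[ f_ij(A,B) / (f_i(A) f_j(B)) ]`` with
    0 log 0 = 0 for plug-in (zero-pseudocount) frequencies. With ``apc`` the
    same average product correction as for Fapc is subtracted.
    """
    fi, fij = freq.fi, freq.fij
    prod = fi[:, None, :, None] * fi[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fij > 0, fij / np.where(prod > 0, prod, 1.0), 1.0)
        terms = np.where(fij > 0, fij * np.log(ratio), 0.0)
    mi = terms.sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    mi = 0.5 * (mi + mi.T)
    scores = mi - _apc(mi) if apc else mi
    np.fill_diagonal(scores, np.nan)
    return ScoreMatrix(scores=scores, kind="MIapc" if apc else "MI")


def score_alignment(aln: Alignment, method: str = "dca", pseudocount: float = 0.5,
                    reweight_threshold: float = 0.9,
                    include_gap: bool = True) -> ScoreMatrix:
    """One-call pipeline: weights -> frequencies -> score matrix.

    ``method`` is one of ``dca`` (Fapc), ``mi``, ``miapc``.
    """
    method = method.lower()
    if method not in ("dca", "mi", "miapc"):
        raise ParameterError(f"unknown scoring method {method!r}")
    weights = compute_weights(aln, threshold=reweight_threshold)
    freq = compute_frequencies(aln, weights, pseudocount_weight=pseudocount)
    if method == "dca":
        return frobenius_apc_score(mean_field_couplings(freq), include_gap=include_gap)
    return mutual_information(freq, apc=(method == "miapc"))
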