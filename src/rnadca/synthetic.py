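"""Synthetic alignments, structures and coordinate fixtures with known truth.

The generator emulates the statistical structure of a curated riboswitch
family: planted nested base pairs with strong Watson-Crick/wobble
covariation, weaker directly-coupled "tertiary" pairs, transitive (indirect)
correlations arising automatically from the coupling graph, phylogenetic
redundancy as duplicated-plus-mutated rows, and a low gap rate. Sequences
are drawn from the same Potts model family that mean-field DCA fits, by
vectorised Gibbs sampling (one independent chain per sequence by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import ALPHABET, GAP
from .alignment import Alignment
from .errors import ParameterError
from .structures import CuratedStructure, crosses

# Non-gap states in sampling order (indices into ALPHABET are +1).
_LETTERS = ("A", "C", "G", "U")
_COMPLEMENT = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def watson_crick_coupling(strength: float, wobble_factor: float = 0.5) -> np.ndarray:
    """4x4 coupling favouring complementary nucleotide combinations."""
    e = np.zeros((4, 4))
    for a, la in enumerate(_LETTERS):
        for b, lb in enumerate(_LETTERS):
            if (la, lb) in _COMPLEMENT:
                e[a, b] = strength
            elif (la, lb) in _WOBBLE:
                e[a, b] = strength * wobble_factor
    return e


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic family.

    Defaults emulate a mid-sized Rfam riboswitch family: 70 nucleotides,
    1000 sequences, strong WC covariation on helices, much weaker couplings
    on a handful of tertiary pairs, 30% near-duplicate rows and a 2% gap
    rate. ``secondary_pairs``/``tertiary_pairs`` of None means "lay out a
    default riboswitch-like fold" (three hairpins inside a closing stem,
    tertiary pairs drawn between loop regions so they pass the |i-j| >= 5
    and secondary-neighbourhood filters by construction).
    """

    n: int = 70
    M: int = 1000
    seed: int = 0
    secondary_pairs: list[tuple[int, int]] | None = None
    tertiary_pairs: list[tuple[int, int]] | None = None
    n_tertiary: int = 6
    secondary_strength: float = 2.0
    wobble_factor: float = 0.5
    tertiary_strength: float = 0.5
    field_sd: float = 0.2
    redundancy_rate: float = 0.3
    duplicate_mutation_rate: float = 0.02
    gap_rate: float = 0.02
    burn_in: int = 1000
    thinning: int = 10
    n_chains: int | None = None  # default: one independent chain per sequence

    def __post_init__(self) -> None:
        if self.n < 2 or self.M < 1:
            raise ParameterError("need n >= 2 and M >= 1")
        if not (0.0 <= self.redundancy_rate < 1.0):
            raise ParameterError("redundancy_rate must be in [0, 1)")
        if not (0.0 <= self.gap_rate < 1.0):
            raise ParameterError("gap_rate must be in [0, 1)")


def default_secondary_structure(n: int) -> list[tuple[int, int]]:
    """A nested riboswitch-like layout: closing stem plus hairpins (0-based)."""
    if n < 30:
        raise ParameterError("default secondary layout needs n >= 30")
    pairs = [(2 + k, n - 3 - k) for k in range(4)]  # closing stem
    inner_lo, inner_hi = 8, n - 9
    cursor = inner_lo
    while inner_hi - cursor >= 14:
        span = min(15, inner_hi - cursor)
        helix = 4
        for k in range(helix):
            pairs.append((cursor + k, cursor + span - 1 - k))
        cursor += span + 2  # spacer between hairpins
    return sorted(pairs)


def _pick_tertiary_pairs(n: int, secondary: list[tuple[int, int]], count: int,
                         rng: np.random.Generator) -> list[tuple[int, int]]:
    """Random pairs that survive the near-diagonal and ss-neighbourhood filters."""
    occupied = {p for pair in secondary for p in pair}
    candidates = []
    for i in range(n):
        for j in range(i + 5, n):
            if i in occupied or j in occupied:
                continue
            if any((abs(i - k) <= 2 and abs(j - l) <= 2) or
                   (abs(i - l) <= 2 and abs(j - k) <= 2) for k, l in secondary):
                continue
            candidates.append((i, j))
    if len(candidates) < count:
        raise ParameterError("not enough positions for the requested tertiary pairs")
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for idx in rng.permutation(len(candidates)):
        i, j = candidates[idx]
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
        if len(chosen) == count:
            break
    if len(chosen) < count:
        raise ParameterError("could not place disjoint tertiary pairs")
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def sample_potts(couplings: dict[tuple[int, int], np.ndarray], fields: np.ndarray,
                 M: int, rng: np.random.Generator, burn_in: int = 1000,
                 thinning: int = 10, n_chains: int | None = None) -> np.ndarray:
    """Draw M sequences from a Potts model over the 4 nucleotide states.

    ``couplings`` maps (i, j) with i < j to a 4x4 matrix e_ij(A_i, A_j);
    ``fields`` is (n, 4). Sampling runs ``n_chains`` independent Gibbs
    chains (default: M, one per sequence) vectorised over chains, each for
    ``burn_in`` full sweeps; when fewer chains than sequences are used,
    additional draws per chain are separated by ``thinning`` sweeps.
    Returns an (M, n) int array of states 0..3.
    """
    n = fields.shape[0]
    chains = M if n_chains is None else n_chains
    if chains < 1:
        raise ParameterError("need at least one chain")
    partners: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(n)]
    for (i, j), e in couplings.items():
        if not (0 <= i < j < n) or e.shape != (4, 4):
            raise ParameterError(f"bad coupling entry for pair {(i, j)}")
        partners[i].append((j, e))
        partners[j].append((i, e.T))

    state = rng.integers(0, 4, size=(chains, n))

    def sweep() -> None:
        for i in range(n):
            E = np.broadcast_to(fields[i], (chains, 4)).copy()
            for j, e in partners[i]:
                E += e[:, state[:, j]].T
            E -= E.max(axis=1, keepdims=True)
            p = np.exp(E)
            cum = np.cumsum(p, axis=1)
            u = rng.random(chains) * cum[:, -1]
            state[:, i] = (cum < u[:, None]).sum(axis=1)

    for _ in range(burn_in):
        sweep()
    samples = [state.copy()]
    while sum(s.shape[0] for s in samples) < M:
        for _ in range(thinning):
            sweep()
        samples.append(state.copy())
    return np.concatenate(samples, axis=0)[:M]


def _enumerate_potts(couplings: dict[tuple[int, int], np.ndarray],
                     fields: np.ndarray) -> np.ndarray:
    """Exact Boltzmann distribution by enumeration (tiny n only)."""
    n = fields.shape[0]
    if n > 8:
        raise ParameterError("exact enumeration limited to n <= 8")
    shape = (4,) * n
    logp = np.zeros(shape)
    for i in range(n):
        dims = [1] * n
        dims[i] = 4
        logp += fields[i].reshape(dims)
    for (i, j), e in couplings.items():
        logp += _pair_term(e, i, j, n)
    p = np.exp(logp - logp.max())
    return p / p.sum()


def _pair_term(e: np.ndarray, i: int, j: int, n: int) -> np.ndarray:
    dims = [1] * n
    dims[i], dims[j] = 4, 4
    if i < j:
        return e.reshape(dims)
    return e.T.reshape(dims)


def exact_potts_distribution(couplings: dict[tuple[int, int], np.ndarray],
                             fields: np.ndarray) -> np.ndarray:
    """Public wrapper for the exact joint distribution (n <= 8)."""
    return _enumerate_potts(couplings, fields)


# ---------------------------------------------------------------------------
# Alignment generation
# ---------------------------------------------------------------------------

def sample_potts_alignment(spec: GeneratorSpec) -> tuple[Alignment, dict]:
    """Generate a synthetic family alignment plus its ground truth.

    Row 0 (``target``) is kept gap-free so that every alignment column maps
    onto a target position. Returns the alignment and a truth dict holding
    the planted secondary/tertiary pairs, the coupling graph and a sampling
    manifest (seed, burn-in, thinning, chain count, duplicate rows).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    secondary = (default_secondary_structure(n) if spec.secondary_pairs is None
                 else sorted(tuple(sorted(p)) for p in spec.secondary_pairs))
    for a, p in enumerate(secondary):
        for q in secondary[a + 1:]:
            if crosses(p, q):
                raise ParameterError("planted secondary pairs must be nested")
    tertiary = (_pick_tertiary_pairs(n, secondary, spec.n_tertiary, rng)
                if spec.tertiary_pairs is None
                else sorted(tuple(sorted(p)) for p in spec.tertiary_pairs))

    couplings: dict[tuple[int, int], np.ndarray] = {}
    wc = watson_crick_coupling(spec.secondary_strength, spec.wobble_factor)
    for p in secondary:
        couplings[p] = wc.copy()
    for p in tertiary:
        couplings[p] = rng.normal(0.0, spec.tertiary_strength, size=(4, 4))
    fields = rng.normal(0.0, spec.field_sd, size=(n, 4))

    n_dup = int(round(spec.redundancy_rate * spec.M))
    m_base = spec.M - n_dup
    if m_base < 1:
        raise ParameterError("redundancy rate leaves no independent sequences")
    states = sample_potts(couplings, fields, m_base, rng, burn_in=spec.burn_in,
                          thinning=spec.thinning, n_chains=spec.n_chains)

    letters = np.array(_LETTERS)
    rows = [list(letters[s]) for s in states]
    dup_sources = rng.integers(0, m_base, size=n_dup)
    for src in dup_sources:
        dup = list(rows[src])
        mut = rng.random(n) < spec.duplicate_mutation_rate
        for pos in np.nonzero(mut)[0]:
            dup[pos] = str(rng.choice(letters))
        rows.append(dup)
    # gap injection, skipping the gap-free target row 0
    for m in range(1, len(rows)):
        gaps = rng.random(n) < spec.gap_rate
        for pos in np.nonzero(gaps)[0]:
            rows[m][pos] = GAP

    ids = ["target"] + [f"seq{m:05d}" for m in range(1, spec.M)]
    aln = Alignment(sequence_ids=ids, rows=["".join(r) for r in rows],
                    consensus_structure=list(secondary))
    truth = {
        "secondary_pairs": secondary,
        "tertiary_pairs": tertiary,
        "coupling_pairs": sorted(couplings),
        "manifest": {
            "seed": spec.seed, "n": n, "M": spec.M, "m_base": m_base,
            "n_duplicates": n_dup, "burn_in": spec.burn_in,
            "thinning": spec.thinning,
            "n_chains": spec.n_chains if spec.n_chains is not None else m_base,
            "secondary_strength": spec.secondary_strength,
            "tertiary_strength": spec.tertiary_strength,
            "gap_rate": spec.gap_rate,
            "redundancy_rate": spec.redundancy_rate,
        },
    }
    return aln, truth


# ---------------------------------------------------------------------------
# PDB fixtures
# ---------------------------------------------------------------------------

def make_pdb_fixture(pairs_in_contact: list[tuple[int, int]], n: int, seed: int = 0,
                     contact_distance: float = 3.0, spacing: float = 20.0,
                     sequence: str | None = None, chain: str = "A") -> str:
    """Minimal synthetic single-chain PDB text with one pseudo-atom per residue.

    Residues sit on a line ``spacing`` Angstrom apart; for the k-th requested
    contact pair (i, j) residue j is moved next to residue i at exactly
    ``contact_distance``, along an axis direction cycling per pair so the
    distance is exact at the 3-decimal PDB coordinate precision. Pairs must
    be residue-disjoint for the distances to be guaranteed.
    """
    if sequence is None:
        sequence = "".join(np.random.default_rng(seed).choice(list(_LETTERS), size=n))
    if len(sequence) != n:
        raise ParameterError("sequence length must equal n")
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    axes = [np.array(v, dtype=float) for v in
            ((0, 1, 0), (0, 0, 1), (0, -1, 0), (0, 0, -1))]
    seen: set[int] = set()
    for k, (i, j) in enumerate(pairs_in_contact):
        i, j = sorted((i, j))
        if not (0 <= i < j < n):
            raise ParameterError(f"contact pair {(i, j)} out of range")
        if i in seen or j in seen:
            raise ParameterError("contact pairs must be residue-disjoint")
        seen.update((i, j))
        coords[j] = coords[i] + contact_distance * axes[k % len(axes)]
    lines = ["REMARK synthetic single-atom-per-residue fixture"]
    for i in range(n):
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:>5}  C1' {sequence[i]:>3} {chain}{i + 1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C")
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def write_fixture_bundle(spec: GeneratorSpec, out_dir: str | Path,
                         header: str | None = None) -> dict:
    """Generate and write .sto, .ct, .pdb and truth.json for one family."""
    from .alignment import write_alignment
    from .structures import write_secondary_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, truth = sample_potts_alignment(spec)
    target = aln.rows[0]
    write_alignment(aln, out / "family.sto", "stockholm", header=header)
    write_secondary_structure(
        CuratedStructure(truth["secondary_pairs"], sequence=target),
        out / "secondary.ct", "ct", name="planted", header=header)
    pdb = make_pdb_fixture(truth["tertiary_pairs"], spec.n, seed=spec.seed,
                           sequence=target)
    (out / "structure.pdb").write_text(pdb)
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
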