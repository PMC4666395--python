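import numpy as np
import pytest

from rnadca.alignment import build_column_map
from rnadca.synthetic import GeneratorSpec, sample_potts_alignment


@pytest.fixture(scope="session")
def riboswitch_family():
    """One synthetic riboswitch-like family shared across tests.

    Session-scoped because Gibbs sampling dominates test runtime; tests must
    not mutate the returned objects.
    """
    spec = GeneratorSpec(n=70, M=1000, seed=11, burn_in=300)
    aln, truth = sample_potts_alignment(spec)
    cmap = build_column_map(aln, "target")
    return aln, truth, cmap


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_fasta(tmp_path, rows, ids=None, name="aln.fasta"):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    path = tmp_path / name
    path.write_text("".join(f">{i}\n{r}\n" for i, r in zip(ids, rows)))
    return path


def make_stockholm(tmp_path, rows, ss=None, ids=None, rf=None, name="aln.sto"):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    lines = ["# STOCKHOLM 1.0"]
    for i, r in zip(ids, rows):
        lines.append(f"{i:<14}{r}")
    if rf is not None:
        lines.append(f"{'#=GC RF':<14}{rf}")
    if ss is not None:
        lines.append(f"{'#=GC SS_cons':<14}{ss}")
    lines.append("//")
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


def random_nested_pairs(n, rng, min_loop=3, p_pair=0.6):
    """Random nested, loop-legal pair set by recursive splitting."""
    pairs = []

    def rec(i, j):
        if j - i < min_loop + 1:
            return
        if rng.random() < p_pair:
            pairs.append((i, j))
            rec(i + 1, j - 1)
        else:
            k = int(rng.integers(i, j))
            rec(i, k)
            rec(k + 1, j)

    rec(0, n - 1)
    return sorted(pairs)
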