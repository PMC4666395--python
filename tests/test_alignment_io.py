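"""Alignment/structure parsing, normalization, column mapping and curation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnadca.alignment import build_column_map, read_alignment, write_alignment
from rnadca.errors import (AlignmentFormatError, RnaDcaError,
                           StructureFormatError)
from rnadca.structures import (CuratedStructure, curate_consensus,
                               dotbracket_to_pairs, pairs_to_dotbracket,
                               parse_wuss, read_secondary_structure,
                               write_secondary_structure)

from conftest import make_fasta, make_stockholm, random_nested_pairs


class TestReadAlignment:
    def test_fasta_alphabet_normalization(self, tmp_path):
        path = make_fasta(tmp_path, ["ACGT", "acgu", "ACGN"])
        aln = read_alignment(path)
        assert aln.rows == ["ACGU", "ACGU", "ACG-"]
        assert (aln.M, aln.L) == (3, 4)

    def test_alphabet_closure(self, tmp_path):
        path = make_fasta(tmp_path, ["RYN.WS*x", "ACGUacgu"])
        aln = read_alignment(path)
        assert set("".join(aln.rows)) <= set("ACGU-")

    def test_stockholm_ss_cons(self, tmp_path):
        path = make_stockholm(tmp_path, ["GGAAACC", "GGAAACC"], ss="((...))")
        aln = read_alignment(path)
        assert aln.consensus_structure == [(0, 6), (1, 5)]
        assert aln.crossing_pairs == []

    def test_wuss_crossing_pair_separated(self, tmp_path):
        # columns 1-8 nested helix, 5-11 crossing (1-based)
        path = make_stockholm(tmp_path, ["GGAAUAACCAU"], ss="((..[.))..]")
        aln = read_alignment(path)
        assert aln.consensus_structure == [(0, 7), (1, 6)]
        assert aln.crossing_pairs == [(4, 10)]

    def test_pseudoknot_letters_go_to_crossing(self):
        nested, crossing = parse_wuss("AA...aa....")
        assert nested == []
        assert crossing == [(0, 6), (1, 5)]

    def test_unmatched_bracket_raises(self, tmp_path):
        path = make_stockholm(tmp_path, ["GGAAACC"], ss="((....)")
        with pytest.raises(StructureFormatError):
            read_alignment(path)

    def test_ragged_fasta_raises(self, tmp_path):
        path = make_fasta(tmp_path, ["ACGU", "ACG"])
        with pytest.raises(AlignmentFormatError):
            read_alignment(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_alignment(path)

    def test_rf_insert_columns_dropped(self, tmp_path):
        path = make_stockholm(tmp_path, ["AC.GU", "ACAGU"],
                              rf="XX.XX", ss="((.))")
        aln = read_alignment(path)
        assert aln.L == 4
        assert aln.rows == ["ACGU", "ACGU"]
        assert list(aln.column_mask) == [0, 1, 3, 4]
        assert aln.consensus_structure == [(0, 3), (1, 2)]


class TestColumnMap:
    def test_gapped_row(self, tmp_path):
        aln = read_alignment(make_fasta(tmp_path, ["A-CG", "AUCG"]))
        cmap = build_column_map(aln, "s0")
        assert cmap.target_sequence == "ACG"
        assert list(cmap.col_to_pos) == [0, -1, 1, 2]
        assert list(cmap.pos_to_col) == [0, 2, 3]

    def test_identity_on_ungapped_row(self, tmp_path):
        aln = read_alignment(make_fasta(tmp_path, ["AUCG"]))
        cmap = build_column_map(aln, "s0")
        assert list(cmap.col_to_pos) == [0, 1, 2, 3]

    def test_strictly_increasing_and_inverse(self, tmp_path):
        aln = read_alignment(make_fasta(tmp_path, ["A--UC-GA-U"]))
        cmap = build_column_map(aln, "s0")
        defined = cmap.col_to_pos[cmap.col_to_pos >= 0]
        assert np.all(np.diff(defined) > 0)
        for c in np.nonzero(cmap.col_to_pos >= 0)[0]:
            assert cmap.pos_to_col[cmap.col_to_pos[c]] == c

    def test_all_gap_row_raises(self, tmp_path):
        aln = read_alignment(make_fasta(tmp_path, ["----", "ACGU"]))
        with pytest.raises(RnaDcaError, match="all gaps"):
            build_column_map(aln, "s0")

    def test_unknown_id_raises(self, tmp_path):
        aln = read_alignment(make_fasta(tmp_path, ["ACGU"]))
        with pytest.raises(LookupError):
            build_column_map(aln, "nope")


class TestCurateConsensus:
    def test_keep_and_remove(self, tmp_path):
        # consensus pairs (0,6) and (1,5); target makes (0,6)=G,C ok and (1,5)=A,G not
        path = make_stockholm(tmp_path, ["GAUUUGC", "GCUUUGC"], ss="((...))")
        aln = read_alignment(path)
        cs = curate_consensus(aln, build_column_map(aln, "s0"))
        assert cs.base_pairs == [(0, 6)]
        assert cs.provenance[(0, 6)] == "consensus-kept"
        assert cs.provenance[(1, 5)] == "removed-incompatible"

    def test_unmappable_end_dropped(self, tmp_path):
        path = make_stockholm(tmp_path, ["-AUUUGC", "GCUUUGC"], ss="((...))")
        aln = read_alignment(path)
        cs = curate_consensus(aln, build_column_map(aln, "s0"))
        assert (0, 6) not in {tuple(p) for p in cs.base_pairs}

    def test_helix_extension_fixture(self, tmp_path):
        # helix (1,8),(2,7) on GGGAAAACCC-like target; extension inward blocked
        # by the loop, outward (0,9) compatible -> added
        path = make_stockholm(tmp_path, ["GGGAAAACCC"], ss=".((....)).")
        aln = read_alignment(path)
        cmap = build_column_map(aln, "s0")
        plain = curate_consensus(aln, cmap, extend_helices=False)
        assert plain.base_pairs == [(1, 8), (2, 7)]
        ext = curate_consensus(aln, cmap, extend_helices=True)
        # exhaustive check: candidates are (0,9) G-C ok, (3,6) A-A no
        assert ext.base_pairs == [(0, 9), (1, 8), (2, 7)]
        assert ext.provenance[(0, 9)] == "helix-extension"

    def test_output_always_valid(self, riboswitch_family):
        aln, _, cmap = riboswitch_family
        cs = curate_consensus(aln, cmap, extend_helices=True)
        cs.validate()  # WC/wobble, exclusive, nested


class TestStructureFiles:
    def test_dotbracket_basic(self, tmp_path):
        p = tmp_path / "s.db"
        p.write_text("(((...)))\n")
        cs = read_secondary_structure(p)
        assert cs.base_pairs == [(0, 8), (1, 7), (2, 6)]

    def test_ct_unpaired_row(self, tmp_path):
        p = tmp_path / "s.ct"
        p.write_text("5 test\n1 A 0 2 0 1\n2 C 1 3 0 2\n3 G 2 4 0 3\n"
                     "4 U 3 5 0 4\n5 A 4 6 0 5\n")
        cs = read_secondary_structure(p)
        assert cs.base_pairs == []
        assert cs.sequence == "ACGUA"

    def test_ct_conflicting_pairs_raise(self, tmp_path):
        p = tmp_path / "bad.ct"
        p.write_text("5 t\n1 G 0 2 5 1\n2 C 1 3 0 2\n3 G 2 4 0 3\n"
                     "4 U 3 5 0 4\n5 C 4 6 2 5\n")
        with pytest.raises(StructureFormatError, match="conflict"):
            read_secondary_structure(p)

    def test_ct_position_out_of_range(self, tmp_path):
        p = tmp_path / "bad.ct"
        p.write_text("2 t\n1 A 0 2 9 1\n2 C 1 3 0 2\n")
        with pytest.raises(StructureFormatError):
            read_secondary_structure(p)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), fmt=st.sampled_from(["dotbracket", "ct"]))
    def test_roundtrip_random_nested(self, seed, fmt, tmp_path_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        pairs = random_nested_pairs(n, rng)
        seq = _compatible_sequence(n, pairs, rng)
        cs = CuratedStructure(pairs, sequence=seq)
        p = tmp_path_factory.mktemp("rt") / ("s.ct" if fmt == "ct" else "s.db")
        write_secondary_structure(cs, p, fmt)
        back = read_secondary_structure(p, fmt)
        assert back.base_pairs == cs.base_pairs
        assert back.sequence == seq

    def test_dotbracket_string_roundtrip(self, rng):
        pairs = random_nested_pairs(40, rng)
        s = pairs_to_dotbracket(pairs, 40)
        assert dotbracket_to_pairs(s) == pairs


class TestAlignmentRoundtrip:
    @pytest.mark.parametrize("fmt", ["fasta", "stockholm"])
    def test_read_write_identity(self, tmp_path, fmt, riboswitch_family):
        aln = riboswitch_family[0]
        p = tmp_path / f"out.{'sto' if fmt == 'stockholm' else 'fasta'}"
        write_alignment(aln, p, fmt)
        back = read_alignment(p, fmt)
        assert back.rows == aln.rows
        assert back.sequence_ids == aln.sequence_ids
        if fmt == "stockholm":
            assert back.consensus_structure == aln.consensus_structure


def _compatible_sequence(n, pairs, rng):
    import numpy as np
    seq = list(rng.choice(list("ACGU"), size=n))
    for i, j in pairs:
        seq[i], seq[j] = ("G", "C") if rng.random() < 0.5 else ("A", "U")
    return "".join(seq)
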