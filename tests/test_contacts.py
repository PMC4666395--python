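"""Contact maps, tertiary-pair filtering, enrichment statistics, restraints."""

import itertools
import math

import numpy as np
import pytest

from rnadca.alignment import Alignment, build_column_map
from rnadca.coevolution import ScoreMatrix
from rnadca.contacts import (RankedPair, RankedPairList, binomial_tail,
                             contact_map_from_pdb, enrichment_scan,
                             filter_and_rank, format_restraints,
                             map_chain_to_target, read_restraints,
                             tp_rate_curve, write_restraints)
from rnadca.errors import MappingError, ParameterError
from rnadca.structures import CuratedStructure
from rnadca.synthetic import make_pdb_fixture


def write_pdb(tmp_path, text, name="f.pdb"):
    p = tmp_path / name
    p.write_text(text)
    return p


def full_score_matrix(L, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    s = rng.uniform(0.1, 1.0, size=(L, L))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, np.nan)
    return ScoreMatrix(scores=s, kind="Fapc")


def identity_cmap(seq):
    aln = Alignment(["t"], [seq])
    return build_column_map(aln, "t")


class TestContactMap:
    def test_two_residue_distance(self, tmp_path):
        pdb = write_pdb(tmp_path, make_pdb_fixture([(0, 1)], 2, contact_distance=3.0))
        cm = contact_map_from_pdb(pdb, "A")
        assert cm.dist[0, 1] == pytest.approx(3.0, abs=1e-9)

    def test_four_residue_table_matches_bruteforce(self, tmp_path):
        text = make_pdb_fixture([(0, 2)], 4, contact_distance=4.5)
        pdb = write_pdb(tmp_path, text)
        cm = contact_map_from_pdb(pdb, "A")
        # independent oracle: parse coordinates straight off the ATOM records
        coords = [np.array([float(l[30:38]), float(l[38:46]), float(l[46:54])])
                  for l in text.splitlines() if l.startswith("ATOM")]
        for i in range(4):
            for j in range(i + 1, 4):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                assert cm.dist[i, j] == pytest.approx(d, abs=1e-9)

    @staticmethod
    def atom_line(record, serial, name, resname, resseq, x, element):
        return (f"{record:<6}{serial:>5} {name:<4} {resname:>3} A{resseq:>4}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2}")

    def test_hydrogen_only_residue_unresolved(self, tmp_path):
        lines = [self.atom_line("ATOM", 1, " C1'", "A", 1, 0.0, "C"),
                 self.atom_line("ATOM", 2, " H1'", "G", 2, 3.0, "H"),
                 self.atom_line("ATOM", 3, " C1'", "C", 3, 6.0, "C"),
                 "END"]
        cm = contact_map_from_pdb(write_pdb(tmp_path, "\n".join(lines) + "\n"), "A")
        assert cm.n == 3
        assert cm.resolved == {0, 2}
        assert np.isnan(cm.dist[0, 1])

    def test_hetero_residues_skipped(self, tmp_path):
        lines = [self.atom_line("ATOM", 1, " C1'", "A", 1, 0.0, "C"),
                 self.atom_line("HETATM", 2, " O", "HOH", 101, 1.0, "O"),
                 self.atom_line("ATOM", 3, " C1'", "U", 2, 5.0, "C"),
                 "END"]
        cm = contact_map_from_pdb(write_pdb(tmp_path, "\n".join(lines) + "\n"), "A")
        assert cm.sequence == "AU"

    def test_missing_chain_raises(self, tmp_path):
        pdb = write_pdb(tmp_path, make_pdb_fixture([], 3))
        with pytest.raises(MappingError):
            contact_map_from_pdb(pdb, "B")

    def test_chain_offset_matching(self, tmp_path):
        pdb = write_pdb(tmp_path, make_pdb_fixture([], 4, sequence="ACGU"))
        cm = contact_map_from_pdb(pdb, "A")
        assert map_chain_to_target(cm, "ACGU") == 0
        assert map_chain_to_target(cm, "GGACGU") == 2
        with pytest.raises(MappingError):
            map_chain_to_target(cm, "UUUU")


class TestFilterAndRank:
    def make_inputs(self, tmp_path, n=40, ss_pairs=(), contacts=(), seed=0):
        seq = "GC" * (n // 2)
        cmap = identity_cmap(seq)
        sm = full_score_matrix(n, seed=seed)
        ss = CuratedStructure(list(ss_pairs), n=n)
        pdb = write_pdb(tmp_path, make_pdb_fixture(list(contacts), n,
                                                   sequence=seq))
        cm = contact_map_from_pdb(pdb, "A")
        return sm, cmap, ss, cm

    def test_near_diagonal_boundary(self, tmp_path):
        sm, cmap, ss, cm = self.make_inputs(tmp_path)
        rpl = filter_and_rank(sm, cmap, ss, cm)
        kept = {(p.i, p.j) for p in rpl.pairs}
        assert (0, 4) not in kept and (0, 4) in set(rpl.excluded["near-diagonal"])
        assert (0, 5) in kept

    def test_ss_neighborhood_rule(self, tmp_path):
        # ss pair at (9,19) 0-based; (11,17) is within +/-2 of both ends
        sm, cmap, ss, cm = self.make_inputs(tmp_path, ss_pairs=[(9, 19)])
        rpl = filter_and_rank(sm, cmap, ss, cm)
        kept = {(p.i, p.j) for p in rpl.pairs}
        assert (11, 17) not in kept
        assert (11, 17) in set(rpl.excluded["ss-neighborhood"])
        assert (12, 17) in kept

    def test_exclusions_match_bruteforce(self, tmp_path):
        ss_pairs = [(5, 30), (6, 29), (14, 22)]
        sm, cmap, ss, cm = self.make_inputs(tmp_path, ss_pairs=ss_pairs)
        rpl = filter_and_rank(sm, cmap, ss, cm)
        kept = {(p.i, p.j) for p in rpl.pairs}
        # independent brute-force filter over all candidate pairs
        expect_kept = set()
        for i, j in itertools.combinations(range(40), 2):
            if abs(i - j) < 5:
                continue
            if any((abs(i - k) <= 2 and abs(j - l) <= 2) or
                   (abs(i - l) <= 2 and abs(j - k) <= 2) for k, l in ss_pairs):
                continue
            expect_kept.add((i, j))
        assert kept == expect_kept
        # the "25 pairs" neighbourhood of an interior ss pair
        k, l = 14, 22
        neigh = {(min(a, b), max(a, b))
                 for a in range(k - 2, k + 3) for b in range(l - 2, l + 3)}
        assert kept & neigh == set()

    def test_bookkeeping_partition(self, tmp_path):
        sm, cmap, ss, cm = self.make_inputs(tmp_path, ss_pairs=[(5, 30)])
        rpl = filter_and_rank(sm, cmap, ss, cm)
        n_candidates = 40 * 39 // 2
        n_excluded = sum(len(v) for v in rpl.excluded.values())
        assert len(rpl.pairs) + n_excluded == n_candidates

    def test_threshold_nesting(self, tmp_path):
        contacts = [(0, 10), (20, 35)]
        sm, cmap, ss, cm = self.make_inputs(tmp_path, contacts=contacts)
        tp4 = {(p.i, p.j) for p in filter_and_rank(sm, cmap, ss, cm, 4.0).pairs
               if p.is_tp}
        tp8 = {(p.i, p.j) for p in filter_and_rank(sm, cmap, ss, cm, 8.0).pairs
               if p.is_tp}
        assert tp4 <= tp8
        assert tp8 == set(contacts)

    def test_score_descending_with_deterministic_ties(self, tmp_path):
        sm, cmap, ss, cm = self.make_inputs(tmp_path)
        rpl = filter_and_rank(sm, cmap, ss, cm)
        scores = [p.score for p in rpl.pairs]
        assert scores == sorted(scores, reverse=True)


def rpl_from_labels(labels, scores=None):
    scores = scores or [float(len(labels) - k) for k in range(len(labels))]
    pairs = [RankedPair(k, k + 20, s, float(k), bool(l))
             for k, (l, s) in enumerate(zip(labels, scores))]
    return RankedPairList(pairs=pairs, excluded={}, threshold=8.0,
                          target_sequence="A" * (len(labels) + 25))


class TestTpRateCurve:
    def test_all_tp_constant_one(self):
        curve = tp_rate_curve(rpl_from_labels([1, 1, 1, 1]))
        assert np.allclose(curve["precision"], 1.0)

    def test_small_example(self):
        curve = tp_rate_curve(rpl_from_labels([1, 0, 1]))
        assert np.allclose(curve["precision"], [1.0, 0.5, 2 / 3])

    def test_prefix_mean_oracle_and_dominance(self, rng):
        labels = (rng.random(200) < 0.3).astype(int)
        # TPs get small distances so the distance ranking is the oracle
        rpl = rpl_from_labels(labels)
        for p in rpl.pairs:
            p.dist = (2.0 if p.is_tp else 20.0) + 0.01 * p.i
        curve = tp_rate_curve(rpl)
        for k in (1, 7, 50, 200):
            assert curve["precision"][k - 1] == pytest.approx(labels[:k].mean())
        assert np.all(curve["oracle_precision"] >= curve["precision"] - 1e-12)


class TestBinomialTail:
    def test_zero_successes_needed(self):
        assert binomial_tail(0, 10, 0.3) == 1.0

    def test_closed_form_all_successes(self):
        assert binomial_tail(10, 10, 0.5) == pytest.approx(2.0 ** -10, rel=1e-12)

    @pytest.mark.parametrize("y,r0", [(5, 0.3), (11, 0.5), (15, 0.07)])
    def test_matches_outcome_enumeration(self, y, r0):
        # enumerate all 2^y TP/FP window outcomes under i.i.d. r0
        for t in range(y + 2):
            brute = math.fsum(
                math.prod(r0 if o else 1 - r0 for o in outcome)
                for outcome in itertools.product([0, 1], repeat=y)
                if sum(outcome) >= t)
            assert binomial_tail(t, y, r0) == pytest.approx(brute, abs=1e-12)


class TestEnrichmentScan:
    def test_window_rounding_half_up(self):
        scan = enrichment_scan(rpl_from_labels([1] * 25), window_fraction=0.10)
        assert scan.window == 3  # 2.5 rounds half-up
        scan = enrichment_scan(rpl_from_labels([1] * 4), window_fraction=0.10)
        assert scan.window == 1  # floored at 1

    def test_empty_window_p_is_one(self):
        scan = enrichment_scan(rpl_from_labels([0] * 30))
        assert np.allclose(scan.pvalues, 1.0)
        assert scan.first_crossing == 0

    def test_front_loaded_list_crosses_late(self):
        labels = [1] * 10 + [0] * 90
        scan = enrichment_scan(rpl_from_labels(labels))
        assert scan.first_crossing > 0
        assert scan.sensitivity == pytest.approx(
            sum(labels[:scan.first_crossing]) / 10)
        assert scan.precision == pytest.approx(1.0)

    def test_r0_is_residual_tp_fraction(self):
        labels = [1, 0, 1, 0, 0, 1, 0, 0, 0, 0]
        scan = enrichment_scan(rpl_from_labels(labels), window_fraction=0.2)
        for x in scan.offsets:
            assert scan.r0[x] == pytest.approx(sum(labels[x:]) / (10 - x))

    def test_empty_list_raises(self):
        with pytest.raises(ParameterError):
            enrichment_scan(rpl_from_labels([]))


class TestRestraints:
    def test_top_zero_header_only(self, tmp_path):
        rpl = rpl_from_labels([1, 0, 1])
        write_restraints(rpl, 0, tmp_path / "r.tsv", tmp_path / "r.txt",
                         header="cfg")
        lines = (tmp_path / "r.tsv").read_text().splitlines()
        assert lines[0].startswith("#") and lines[1].startswith("i\t")
        assert len(lines) == 2
        assert read_restraints(tmp_path / "r.txt") == []

    def test_roundtrip_both_formats(self, tmp_path):
        rpl = rpl_from_labels([1, 0, 1, 1])
        write_restraints(rpl, 2, tmp_path / "r.tsv", tmp_path / "r.txt")
        for path in (tmp_path / "r.tsv", tmp_path / "r.txt"):
            parsed = read_restraints(path)
            assert [(i, j, u) for _, i, _, j, u in parsed] == \
                [(p.i, p.j, 8.0) for p in rpl.pairs[:2]]

    @pytest.mark.parametrize("top_n", [25, 100])
    def test_line_counts(self, top_n):
        rpl = rpl_from_labels([0] * 120)
        tsv, ros = format_restraints(rpl, top_n)
        assert len(ros.strip().splitlines()) == top_n
        assert len(tsv.strip().splitlines()) == top_n + 1

    def test_atom_rule_wc_edge(self):
        pairs = [RankedPair(0, 20, 1.0, np.nan, False)]
        rpl = RankedPairList(pairs=pairs, excluded={}, threshold=None,
                             target_sequence="G" + "A" * 19 + "C" * 20)
        _, ros = format_restraints(rpl, 1)
        assert ros.startswith("AtomPair N1 1 N3 21 FLAT_HARMONIC")

    def test_top_n_beyond_list_raises(self):
        with pytest.raises(ParameterError):
            format_restraints(rpl_from_labels([1]), 5)
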