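"""Read profiles, the two scores, argmax assignment and pair combination."""

import io
import random

import pytest

from kmersieve.classify import (
    ReadClassification,
    ReadKmerProfile,
    assign_read,
    classify_read,
    combine_pair,
    contamination_score,
    parse_kraken_style,
    read_node_score,
    write_kraken_style,
)
from kmersieve.errors import ParseError, PairingError, UndefinedScoreError
from kmersieve.kmer_index import KmerIndex, ReferenceGenome, build_index
from kmersieve.seqio import SeqRecord

from conftest import random_genome, random_references, random_tree


def profile(read_id="r", l=10, k=3, counts=None, unclassified=0):
    return ReadKmerProfile(read_id, l, k, dict(counts or {}), unclassified)


def empty_index(k=3):
    return KmerIndex(k=k, canonicalize=True, tree_fingerprint="x", entries={})


class TestClassifyRead:
    def test_no_hits_against_empty_index(self):
        p = classify_read(SeqRecord("r", "ATGG", "IIII"), empty_index())
        assert p.node_counts == {} and p.unclassified_count == 2
        assert p.total_possible == 2

    def test_all_windows_hit_single_source_genome(self, star_tree):
        genome = "ACGTACGGTA"
        idx = build_index([ReferenceGenome("g", 101, (genome,))], star_tree, k=3)
        p = classify_read(SeqRecord("r", genome, None), idx)
        assert p.node_counts == {101: 8} and p.unclassified_count == 0

    def test_read_shorter_than_k(self):
        p = classify_read(SeqRecord("r", "AT", None), empty_index(k=3))
        assert p.total_possible == 0 and p.node_counts == {}

    def test_ambiguous_windows_excluded_from_valid(self):
        p = classify_read(SeqRecord("r", "ATNGG", None), empty_index(k=3))
        assert p.valid_windows == 0 and p.total_possible == 3


class TestScores:
    def test_full_match_scores_one(self):
        p = profile(l=4, k=3, counts={101: 2})
        assert read_node_score(p, 101) == 1.0
        assert contamination_score(p) == 1.0

    def test_hand_arithmetic(self):
        p = profile(l=10, k=3, counts={101: 2, 102: 1}, unclassified=5)
        assert read_node_score(p, 101) == pytest.approx(0.25)
        assert read_node_score(p, 102) == pytest.approx(0.125)
        assert read_node_score(p, 999) == 0.0
        assert contamination_score(p) == pytest.approx(0.375)

    def test_undefined_for_zero_windows(self):
        p = profile(l=2, k=3)
        with pytest.raises(UndefinedScoreError):
            read_node_score(p, 101)
        with pytest.raises(UndefinedScoreError):
            contamination_score(p)

    def test_conservation_on_random_profiles(self):
        rng = random.Random(23)
        for _ in range(200):
            k = rng.choice([3, 5, 7])
            l = rng.randint(k, 60)
            total = l - k + 1
            n_hit = rng.randint(0, total)
            counts = {}
            for _ in range(n_hit):
                node = rng.randint(1, 5)
                counts[node] = counts.get(node, 0) + 1
            p = profile(l=l, k=k, counts=counts, unclassified=total - n_hit)
            per_node = sum(read_node_score(p, n) for n in counts)
            assert abs(per_node + p.unclassified_count / total - p.valid_windows / total) < 1e-12
            assert abs(contamination_score(p) - per_node) < 1e-12


class TestAssign:
    def test_strict_maximum(self, star_tree):
        c = assign_read(profile(counts={101: 2, 103: 1}), star_tree)
        assert c.assigned_node == 101 and c.assigned_score == pytest.approx(0.25)
        assert c.contamination_score == pytest.approx(0.375)

    def test_empty_profile_unmatched(self, star_tree):
        c = assign_read(profile(counts={}), star_tree)
        assert c.assigned_node is None
        assert c.assigned_score == 0.0 and c.contamination_score == 0.0

    def test_short_read_unmatched(self, star_tree):
        c = assign_read(profile(l=2, k=3), star_tree)
        assert c.assigned_node is None and c.contamination_score == 0.0

    def test_tie_breaks_deeper_then_smaller_id(self, star_tree):
        # 101 (species, depth 2) vs 11 (genus, depth 1): deeper wins.
        c = assign_read(profile(counts={11: 2, 101: 2}), star_tree)
        assert c.assigned_node == 101
        # equal depth: smaller id wins
        c = assign_read(profile(counts={102: 3, 101: 3}), star_tree)
        assert c.assigned_node == 101

    def test_assigned_score_never_exceeds_contamination(self, star_tree):
        rng = random.Random(31)
        for _ in range(100):
            counts = {n: rng.randint(0, 3) for n in (1, 11, 101, 102)}
            counts = {n: c for n, c in counts.items() if c}
            total = sum(counts.values())
            p = profile(l=total + 12, k=3, counts=counts, unclassified=10)
            c = assign_read(p, star_tree)
            assert c.assigned_score <= c.contamination_score <= 1.0


class TestCombinePair:
    def mk(self, read_id, node, score, contam=None):
        return ReadClassification(read_id, node, score, contam if contam is not None else score)

    def test_max_over_mates_worked_example(self):
        """Mates scoring 0.2 on X and 0.75 on Y combine to 0.75 on Y."""
        c1 = self.mk("p/1", 101, 0.2)
        c2 = self.mk("p/2", 102, 0.75)
        for by in ("contamination-score", "node-score"):
            pair = combine_pair(c1, c2, by=by)
            assert pair.assigned_node == 102
            assert pair.assigned_score == pytest.approx(0.75)
            assert pair.read_id == "p"

    def test_both_unmatched(self):
        pair = combine_pair(self.mk("p/1", None, 0.0), self.mk("p/2", None, 0.0))
        assert pair.assigned_node is None and pair.contamination_score == 0.0

    def test_tie_keeps_first_mate(self):
        pair = combine_pair(self.mk("p/1", 101, 0.5), self.mk("p/2", 102, 0.5))
        assert pair.assigned_node == 101

    def test_commutative_up_to_tie_break(self):
        c1, c2 = self.mk("p/1", 101, 0.2), self.mk("p/2", 102, 0.9)
        a, b = combine_pair(c1, c2), combine_pair(c2, c1)
        assert (a.assigned_node, a.contamination_score) == (
            b.assigned_node,
            b.contamination_score,
        )

    def test_idempotent_on_identical_mates(self):
        c = self.mk("p/1", 101, 0.4)
        pair = combine_pair(c, self.mk("p/2", 101, 0.4))
        assert pair.assigned_node == 101 and pair.assigned_score == 0.4

    def test_mode_changes_winner_when_scores_disagree(self):
        # mate 1: focused match (node score 0.6 = contamination 0.6)
        # mate 2: scattered match (node score 0.3, contamination 0.8)
        c1 = self.mk("p/1", 101, 0.6, contam=0.6)
        c2 = self.mk("p/2", 102, 0.3, contam=0.8)
        assert combine_pair(c1, c2, by="contamination-score").assigned_node == 102
        assert combine_pair(c1, c2, by="node-score").assigned_node == 101

    def test_non_mates_rejected(self):
        with pytest.raises(PairingError):
            combine_pair(self.mk("a/1", 101, 0.2), self.mk("b/2", 102, 0.3))


class TestKrakenStyleIO:
    def test_parse_tokens(self, star_tree):
        lines = ["C\tr1\t101\t10\t101:4 0:4"]
        (p,) = parse_kraken_style(lines, star_tree, k=3)
        assert p.node_counts == {101: 4} and p.unclassified_count == 4
        assert p.read_length == 10

    def test_unclassified_flag_line(self, star_tree):
        (p,) = parse_kraken_style(["U\tr1\t0\t10\t0:8"], star_tree, k=3)
        assert p.node_counts == {} and p.unclassified_count == 8

    def test_ambiguous_tokens_counted_unclassified(self, star_tree):
        (p,) = parse_kraken_style(["C\tr1\t101\t10\t101:3 A:2 0:3"], star_tree, k=3)
        assert p.node_counts == {101: 3} and p.unclassified_count == 5

    @pytest.mark.parametrize(
        "line",
        [
            "C\tr1\t101\tten\t101:4",
            "C\tr1\t101\t10\t101:x",
            "C\tr1\t101\t10\t101:9",  # 9 k-mers impossible for l=10, k=3
            "C\tr1",
        ],
    )
    def test_malformed_lines(self, star_tree, line):
        with pytest.raises(ParseError):
            list(parse_kraken_style([line], star_tree, k=3))

    def test_unknown_taxid_error_or_root(self, star_tree):
        line = ["C\tr1\t999\t10\t999:2"]
        with pytest.raises(ParseError):
            list(parse_kraken_style(line, star_tree, k=3))
        (p,) = parse_kraken_style(line, star_tree, k=3, unknown_taxid="root")
        assert p.node_counts == {1: 2}

    def test_writer_parser_round_trip(self, star_tree):
        rng = random.Random(3)
        refs = random_references(rng, star_tree, [101, 102, 103], (300, 500))
        idx = build_index(refs, star_tree, k=5)
        reads = [
            SeqRecord(f"r{i}", random_genome(rng, 40), None) for i in range(10)
        ] + [SeqRecord("hit", refs[0].sequences[0][:40], None)]
        profiles = [classify_read(r, idx) for r in reads]
        buf = io.StringIO()
        assert write_kraken_style(profiles, star_tree, buf) == len(profiles)
        buf.seek(0)
        parsed = list(parse_kraken_style(buf.read().splitlines(), star_tree, k=5))
        assert [(p.read_id, p.read_length, p.node_counts, p.unclassified_count)
                for p in parsed] == [
            (p.read_id, p.read_length, p.node_counts, p.unclassified_count)
            for p in profiles
        ]


class TestEndToEndCorrectness:
    def test_error_free_reads_classify_to_their_genome(self, star_tree):
        """Reads from one genome score 1.0 on that node when collisions absent."""
        rng = random.Random(77)
        refs = random_references(rng, star_tree, [101, 103], (2000, 2500))
        idx = build_index(refs, star_tree, k=21)
        for ref in refs:
            genome = ref.sequences[0]
            for _ in range(20):
                start = rng.randint(0, len(genome) - 100)
                read = SeqRecord("r", genome[start : start + 100], None)
                c = assign_read(classify_read(read, idx), star_tree)
                assert c.assigned_node == ref.node_id
                assert c.contamination_score == pytest.approx(1.0)
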