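"""k-mer enumeration, canonicalization and exact-index construction."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kmersieve.errors import ConfigError, IndexCompatibilityError, IndexFormatError
from kmersieve.kmer_index import (
    KmerIndex,
    ReferenceGenome,
    build_index,
    canonical_form,
    enumerate_kmers,
    load_index,
    reverse_complement,
    save_index,
)

from conftest import random_genome, random_references, random_tree

kmers = st.text(alphabet="ACGT", min_size=1, max_size=12)


def oracle_index(references, tree, k, canonicalize):
    """Brute force: scan every genome for every k-mer, LCA the hit set."""
    universe = set()
    for ref in references:
        for seq in ref.sequences:
            for km in enumerate_kmers(seq, k):
                universe.add(canonical_form(km) if canonicalize else km)
    entries = {}
    for km in universe:
        hits = set()
        for ref in references:
            for seq in ref.sequences:
                present = {
                    canonical_form(w) if canonicalize else w
                    for w in enumerate_kmers(seq, k)
                }
                if km in present:
                    hits.add(ref.node_id)
        entries[km] = tree.lca(hits)
    return entries


class TestEnumeration:
    def test_printed_3mer_example(self):
        assert enumerate_kmers("ATGG", 3) == ["ATG", "TGG"]

    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AT", 3, []),  # shorter than k
            ("ATNGG", 3, []),  # every window touches the N
            ("ATNGGC", 3, ["GGC"]),  # masking resumes after the N
            ("atgg", 3, ["ATG", "TGG"]),  # case-insensitive input
            ("ACGT", 1, ["A", "C", "G", "T"]),
        ],
    )
    def test_windows_and_ambiguity_masking(self, seq, k, expected):
        assert enumerate_kmers(seq, k) == expected

    def test_count_is_l_minus_k_plus_1_for_clean_sequence(self):
        rng = random.Random(0)
        seq = random_genome(rng, 137)
        for k in (3, 5, 21):
            assert len(enumerate_kmers(seq, k)) == len(seq) - k + 1


class TestCanonical:
    def test_examples(self):
        assert canonical_form("ACG") == "ACG"  # revcomp CGT is larger
        assert canonical_form("TTT") == "AAA"

    @given(kmers)
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_strand_symmetric(self, km):
        c = canonical_form(km)
        assert canonical_form(c) == c
        assert canonical_form(reverse_complement(km)) == c
        assert c <= reverse_complement(c)

    def test_rejects_non_acgt(self):
        with pytest.raises(ConfigError):
            canonical_form("ACN")


class TestBuildIndex:
    def test_single_source_genome(self, star_tree):
        ref = ReferenceGenome("g", 101, ("ACGT",))
        idx = build_index([ref], star_tree, k=3)
        assert idx.entries == {canonical_form("ACG"): 101, canonical_form("CGT"): 101}

    def test_shared_kmer_goes_to_parent(self, star_tree):
        # Siblings 101/102 (parent 11) share GGGCC; each also has private k-mers.
        refs = [
            ReferenceGenome("a", 101, ("GGGCCAA",)),
            ReferenceGenome("b", 102, ("TGGGCCT",)),
        ]
        idx = build_index(refs, star_tree, k=5, canonicalize=False)
        assert idx.entries["GGGCC"] == 11
        assert idx.entries["GGCCA"] == 101
        assert idx.entries["TGGGC"] == 102

    def test_matches_brute_force_oracle(self):
        rng = random.Random(42)
        for trial in range(10):
            tree = random_tree(rng, rng.randint(4, 12))
            leaves = rng.sample(list(tree), rng.randint(2, 4))
            refs = random_references(rng, tree, leaves, (200, 500))
            k = rng.choice([3, 5, 7])
            canon = rng.random() < 0.5
            idx = build_index(refs, tree, k=k, canonicalize=canon)
            assert idx.entries == oracle_index(refs, tree, k, canon)

    def test_monotone_under_database_growth(self, star_tree):
        """Adding a reference only moves entries toward the root."""
        rng = random.Random(5)
        refs = random_references(rng, star_tree, [101, 102], (300, 400))
        extra = random_references(rng, star_tree, [103], (300, 400))
        before = build_index(refs, star_tree, k=3)
        after = build_index(refs + extra, star_tree, k=3)
        for km, node in before.entries.items():
            assert star_tree.is_ancestor(after.entries[km], node)

    def test_reverse_complement_genome_gives_identical_index(self, star_tree):
        rng = random.Random(9)
        seq = random_genome(rng, 400)
        fwd = build_index([ReferenceGenome("g", 101, (seq,))], star_tree, k=7)
        rev = build_index(
            [ReferenceGenome("g", 101, (reverse_complement(seq),))], star_tree, k=7
        )
        assert fwd.entries == rev.entries

    def test_multi_genome_same_node_stays_at_node(self, star_tree):
        refs = [
            ReferenceGenome("a1", 101, ("ACGTACG",)),
            ReferenceGenome("a2", 101, ("ACGTTTT",)),
        ]
        idx = build_index(refs, star_tree, k=4)
        assert set(idx.entries.values()) == {101}

    def test_unknown_node_and_oversized_k(self, star_tree):
        with pytest.raises(IndexCompatibilityError):
            build_index([ReferenceGenome("g", 999, ("ACGT",))], star_tree, k=3)
        with pytest.warns(UserWarning, match="empty"):
            idx = build_index([ReferenceGenome("g", 101, ("ACGT",))], star_tree, k=10)
        assert len(idx) == 0


class TestPersistence:
    def test_round_trip_small_and_empty(self, tmp_path, star_tree):
        small = build_index(
            [ReferenceGenome("g", 101, ("ACGT",))], star_tree, k=3
        )
        with pytest.warns(UserWarning):
            empty = build_index(
                [ReferenceGenome("g", 101, ("AC",))], star_tree, k=5
            )
        for idx, name in ((small, "small"), (empty, "empty")):
            path = tmp_path / f"{name}.ksi"
            save_index(idx, path)
            loaded = load_index(path, tree=star_tree)
            assert loaded.entries == idx.entries
            assert (loaded.k, loaded.canonicalize, loaded.tree_fingerprint) == (
                idx.k,
                idx.canonicalize,
                idx.tree_fingerprint,
            )

    def test_round_trip_random_large(self, tmp_path):
        rng = random.Random(17)
        tree = random_tree(rng, 8)
        refs = random_references(rng, tree, [3, 5, 7], (3000, 4000))
        idx = build_index(refs, tree, k=5)
        path = tmp_path / "big.ksi"
        save_index(idx, path)
        assert load_index(path).entries == idx.entries

    def test_save_is_deterministic(self, tmp_path, star_tree):
        idx = build_index(
            [ReferenceGenome("g", 101, ("ACGTACGTGG",))], star_tree, k=3
        )
        p1, p2 = tmp_path / "a.ksi", tmp_path / "b.ksi"
        save_index(idx, p1)
        save_index(idx, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fingerprint_mismatch_and_corrupt_file(self, tmp_path, star_tree):
        rng = random.Random(1)
        other = random_tree(rng, 5)
        idx = build_index([ReferenceGenome("g", 101, ("ACGTAA",))], star_tree, k=3)
        path = tmp_path / "idx.ksi"
        save_index(idx, path)
        with pytest.raises(IndexCompatibilityError):
            load_index(path, tree=other)
        bad = tmp_path / "bad.ksi"
        bad.write_bytes(b"not gzip at all")
        with pytest.raises(IndexFormatError):
            load_index(bad)
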