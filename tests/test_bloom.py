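"""Bloom filter, counting filter and k-mer graph behaviour."""

import numpy as np
import pytest

from strobeasm.bloom import (BloomFilter, CountingBloomFilter,
                             KmerMultiplicityGraph, build_kmer_graph,
                             canonical_kmer_array, kmer_array, kmer_to_str,
                             revcomp)


class TestBloomFilter:
    def test_no_false_negative_single(self):
        bf = BloomFilter.from_expected(100, 0.01)
        bf.insert(b"ACGTA")
        assert bf.contains(b"ACGTA")

    def test_fresh_filter_negative(self):
        assert not BloomFilter.from_expected(100, 0.01).contains(b"ACGTA")

    def test_zero_capacity_rejected(self):
        with pytest.raises(ValueError):
            BloomFilter(0, 3)
        with pytest.raises(ValueError):
            BloomFilter(100, 0)

    def test_no_false_negatives_bulk(self):
        # 1e5 random insert/query rounds, vectorized
        rng = np.random.default_rng(11)
        keys = rng.integers(0, 2**63, 100_000, dtype=np.uint64)
        bf = BloomFilter.from_expected(100_000, 0.01, seed=2)
        bf.insert_array(keys)
        assert bf.contains_array(keys).all()

    def test_fpr_within_twice_analytic(self):
        rng = np.random.default_rng(5)
        present = rng.integers(0, 2**62, 1000, dtype=np.uint64)
        bf = BloomFilter.from_expected(1000, 0.01, seed=9)
        bf.insert_array(present)
        absent = rng.integers(2**62, 2**63, 10_000, dtype=np.uint64)
        observed = bf.contains_array(absent).mean()
        assert observed <= 2 * max(bf.expected_fpr(), 0.01)
        assert observed <= 0.02

    def test_scalar_matches_vector_path(self):
        bf = BloomFilter.from_expected(500, 0.01, seed=4)
        keys = np.arange(200, dtype=np.uint64) * np.uint64(2654435761)
        bf.insert_array(keys[:100])
        for k in keys:
            assert bf.contains_scalar(int(k)) == bool(
                bf.contains_array(np.array([k]))[0])


class TestCountingBloomFilter:
    def test_count_three(self):
        cbf = CountingBloomFilter.from_expected(100, 0.01)
        for _ in range(3):
            cbf.increment(b"key")
        assert cbf.count(b"key") == 3

    def test_fresh_count_zero(self):
        assert CountingBloomFilter.from_expected(100, 0.01).count(b"key") == 0

    def test_saturation_at_counter_max(self):
        cbf = CountingBloomFilter(1000, counter_bits=8, num_hashes=3)
        for _ in range(300):
            cbf.increment(b"x")
        assert cbf.count(b"x") == 255  # saturated, not wrapped

    def test_one_sided_vs_exact_counts(self):
        # reported count >= true count for every key, under heavy load
        rng = np.random.default_rng(3)
        keys = rng.integers(0, 2**40, 5000, dtype=np.uint64)
        cbf = CountingBloomFilter.from_expected(2000, 0.05, seed=1)
        exact = {}
        for k in keys:
            exact[int(k)] = exact.get(int(k), 0) + 1
        cbf.increment_array(keys)
        for k, true_count in list(exact.items())[:1000]:
            assert cbf.count_scalar(k) >= min(true_count, 255)

    def test_monotone_nondecreasing(self):
        cbf = CountingBloomFilter.from_expected(100, 0.01)
        last = 0
        for _ in range(10):
            cur = cbf.increment(b"k")
            assert cur >= last
            last = cur


class TestKmerGraph:
    def test_direct_enumeration_k5(self):
        g = KmerMultiplicityGraph(k=5, canonical=True, expected_kmers=100)
        g.build(["ACGTACGT"])
        for kmer in ["ACGTA", "CGTAC", "GTACG", "TACGT"]:
            assert g.contains_kmer(kmer)
            counts, valid = g.kmer_multiplicities(kmer)
            assert counts[0] >= 1
        assert not g.contains_kmer("AAAAA")

    def test_repeated_ingest_multiplicity(self):
        g = KmerMultiplicityGraph(k=5, canonical=True, expected_kmers=100)
        g.build(["ACGTACGT"] * 4)
        counts, valid = g.kmer_multiplicities("ACGTACGT")
        assert (counts[valid] >= 4).all()

    def test_neighbors_simple_and_absent(self):
        g = KmerMultiplicityGraph(k=5, canonical=False, expected_kmers=100)
        g.build(["ACGTACGT"])
        nb = g.neighbors("ACGTA", "right")
        assert [n for n, _ in nb] == ["CGTAC"]
        assert nb[0][1] >= 1
        assert g.neighbors("AATTC", "right") == []

    def test_branching_neighbors(self, rnd):
        stem = "A" * 5
        g = KmerMultiplicityGraph(k=5, canonical=False, expected_kmers=1000)
        g.build([stem + "C" + rnd(20, 1), stem + "G" + rnd(20, 2)])
        right = {n[-1] for n, _ in g.neighbors(stem, "right")}
        assert {"C", "G"} <= right

    def test_wrong_length_query_rejected(self):
        g = KmerMultiplicityGraph(k=5, expected_kmers=10)
        g.build(["ACGTACGT"])
        with pytest.raises(ValueError):
            g.neighbors("ACGT", "right")

    def test_n_kmers_skipped(self):
        g = KmerMultiplicityGraph(k=5, canonical=False, expected_kmers=100)
        g.build(["ACGTNACGTACGT"])
        # windows touching the N contribute nothing
        assert not g.contains_kmer("CGTNA")

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_graph([], k=5, expected_kmers=10)

    def test_insertion_order_independence(self, rnd):
        reads = [rnd(60, i) for i in range(5)]
        g1 = KmerMultiplicityGraph(k=7, expected_kmers=1000, seed=3).build(reads)
        g2 = KmerMultiplicityGraph(k=7, expected_kmers=1000, seed=3).build(reads[::-1])
        probe = rnd(2000, 99)
        c1, _ = g1.kmer_multiplicities(probe)
        c2, _ = g2.kmer_multiplicities(probe)
        assert (c1 == c2).all()

    def test_multiplicity_one_sided_vs_hashmap(self, rnd):
        reads = [rnd(300, i) for i in range(10)]
        k = 11
        g = KmerMultiplicityGraph(k=k, canonical=False,
                                  expected_kmers=5000).build(reads)
        exact = {}
        for r in reads:
            for i in range(len(r) - k + 1):
                exact[r[i:i + k]] = exact.get(r[i:i + k], 0) + 1
        for kmer, true_count in exact.items():
            counts, _ = g.kmer_multiplicities(kmer)
            assert counts[0] >= true_count

    def test_bimodal_multiplicities_with_errors(self, rnd):
        from strobeasm.simulate import apply_errors

        truth = rnd(800, 42)
        reads = [apply_errors(truth, np.random.default_rng(i), 0.01, 0, 0)[0]
                 for i in range(100)]
        g = KmerMultiplicityGraph(k=25, canonical=False,
                                  expected_kmers=200_000).build(reads)
        counts, valid = g.kmer_multiplicities(reads[0])
        counts = counts[valid]
        # solid mode far above the weak/error mode
        solid = counts[counts >= 10]
        weak = counts[counts < 10]
        assert solid.size > 0
        assert solid.mean() > 10 * max(weak.mean(), 1) or weak.size == 0

    def test_canonical_strand_collapse(self, rnd):
        s = rnd(100, 8)
        g = KmerMultiplicityGraph(k=9, canonical=True,
                                  expected_kmers=1000).build([s])
        assert g.contains_kmer(revcomp(s)[:9])
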