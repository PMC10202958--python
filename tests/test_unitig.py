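"""Poly(A) signals, overlap-graph construction, reduction and unitigs."""

import itertools

import networkx as nx
import numpy as np
import pytest

from strobeasm import (HEAD_T, NONE, TAIL_A, PolyASignal, assemble_unitigs,
                       build_overlap_graph, detect_polya, find_overlaps,
                       prune_by_polya, transitive_reduce)
from strobeasm.bloom import revcomp


class TestDetectPolya:
    def test_tail_a(self, rnd):
        sig = detect_polya(rnd(300, 1) + "GTC" + "A" * 15)
        assert sig.kind == TAIL_A and sig.tail_length == 15

    def test_head_t(self, rnd):
        assert detect_polya("T" * 12 + rnd(300, 2)).kind == HEAD_T

    def test_random_sequence_none(self, rnd):
        seq = rnd(400, 7)
        # oracle: no terminal window qualifies
        longest_run = max(len(list(g)) for _, g in itertools.groupby(seq))
        assert longest_run < 10
        assert detect_polya(seq).kind == NONE

    def test_tail_precedence_over_head(self, rnd):
        seq = "T" * 15 + rnd(300, 3) + "A" * 15
        assert detect_polya(seq).kind == TAIL_A

    def test_long_tail_measured_past_window(self, rnd):
        sig = detect_polya(rnd(300, 4) + "A" * 40)
        assert sig.kind == TAIL_A and sig.tail_length == 40


def chained_reads(rnd, n=3, seed=11):
    t = rnd(500 + 400 * n, seed)
    return t, [(f"r{i}", t[i * 400:i * 400 + 900]) for i in range(n)]


class TestBuildGraph:
    def test_stranded_path_graph(self, rnd):
        _, reads = chained_reads(rnd)
        ov = find_overlaps(reads, stranded=True)
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads}, stranded=True)
        assert g.number_of_nodes() == 3
        assert sorted(g.edges) == [(("r0", 0), ("r1", 0)),
                                   (("r1", 0), ("r2", 0))]

    def test_unstranded_mirrored(self, rnd):
        _, reads = chained_reads(rnd)
        ov = find_overlaps(reads, stranded=False)
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads},
                                stranded=False)
        assert g.number_of_nodes() == 6
        for u, v in g.edges:
            assert g.has_edge((v[0], 1 - v[1]), (u[0], 1 - u[1]))

    def test_minus_strand_edge_suppressed_when_stranded(self, rnd):
        t = rnd(1300, 9)
        reads = [("A", t[:800]), ("F", revcomp(t[500:1300]))]
        ov = find_overlaps(reads, stranded=False)
        assert len(ov) == 1 and ov[0].strand == "-"
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads},
                                stranded=True)
        assert g.number_of_edges() == 0


class TestPrune:
    def _two_read_graph(self, rnd, ov_reads):
        ov = find_overlaps(ov_reads, stranded=False)
        return build_overlap_graph(ov, {r: len(s) for r, s in ov_reads},
                                   stranded=False)

    def test_tail_a_loses_outgoing(self, rnd):
        _, reads = chained_reads(rnd, n=2)
        g = self._two_read_graph(rnd, reads)
        signals = {"r0": PolyASignal("r0", TAIL_A, 15)}
        before = g.number_of_edges()
        prune_by_polya(g, signals)
        assert not list(g.successors(("r0", 0)))
        assert g.number_of_edges() < before

    def test_antisense_head_to_head_disconnected(self, rnd):
        # convergent genes overlapping antisense at their 3' ends
        core = rnd(400, 20)
        a = rnd(600, 21) + core
        b = rnd(600, 22) + revcomp(core)
        reads = [("A", a), ("B", b)]
        g = self._two_read_graph(rnd, reads)
        assert g.number_of_edges() > 0  # the false join exists pre-pruning
        signals = {"A": PolyASignal("A", TAIL_A, 15),
                   "B": PolyASignal("B", TAIL_A, 15)}
        prune_by_polya(g, signals)
        assert g.number_of_edges() == 0

    def test_no_signals_unchanged(self, rnd):
        _, reads = chained_reads(rnd, n=2)
        g = self._two_read_graph(rnd, reads)
        before = set(g.edges)
        prune_by_polya(g, {})
        assert set(g.edges) == before


def reduction_oracle(g, fuzz=10):
    """Brute-force all-pairs transitive reduction on the same criterion."""
    h = g.copy()
    drop = []
    for u, w in g.edges:
        for v in g.nodes:
            if v in (u, w):
                continue
            if g.has_edge(u, v) and g.has_edge(v, w):
                total = g.edges[u, v]["ext"] + g.edges[v, w]["ext"]
                if abs(total - g.edges[u, w]["ext"]) <= fuzz:
                    drop.append((u, w))
                    break
    h.remove_edges_from(drop)
    return h


def random_string_graph(seed, n_max=30):
    """Random layout-consistent string graph (reads on a line)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    starts = np.sort(rng.integers(0, 2000, n))
    lengths = rng.integers(400, 1200, n)
    g = nx.DiGraph()
    for i in range(n):
        g.add_node(i, length=int(lengths[i]))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            si, ei = starts[i], starts[i] + lengths[i]
            sj, ej = starts[j], starts[j] + lengths[j]
            if si < sj and ei < ej and ei - sj >= 100:  # proper dovetail
                g.add_edge(i, j, ext=int(ej - ei), splice_from=int(ei - sj))
    return g


class TestTransitiveReduction:
    def test_triangle_shortcut_removed(self):
        g = nx.DiGraph()
        g.add_edge("u", "v", ext=100)
        g.add_edge("v", "w", ext=150)
        g.add_edge("u", "w", ext=250)
        transitive_reduce(g)
        assert sorted(g.edges) == [("u", "v"), ("v", "w")]

    def test_plain_path_unchanged(self):
        g = nx.DiGraph()
        g.add_edge("u", "v", ext=100)
        g.add_edge("v", "w", ext=150)
        transitive_reduce(g)
        assert g.number_of_edges() == 2

    def test_inconsistent_shortcut_kept(self):
        g = nx.DiGraph()
        g.add_edge("u", "v", ext=100)
        g.add_edge("v", "w", ext=150)
        g.add_edge("u", "w", ext=500)  # not explained by the two-step path
        transitive_reduce(g)
        assert ("u", "w") in g.edges

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        g = random_string_graph(seed)
        expected = reduction_oracle(g)
        transitive_reduce(g)
        assert set(g.edges) == set(expected.edges)

    @pytest.mark.parametrize("seed", range(10))
    def test_reachability_preserved(self, seed):
        g = random_string_graph(seed + 100)
        before = dict(nx.all_pairs_shortest_path_length(g))
        transitive_reduce(g)
        after = dict(nx.all_pairs_shortest_path_length(g))
        for u in before:
            assert set(before[u]) == set(after.get(u, {u: 0}))


class TestAssembleUnitigs:
    def test_exact_reconstruction(self, rnd):
        t, reads = chained_reads(rnd, n=3, seed=31)
        ov = find_overlaps(reads, stranded=True)
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads},
                                stranded=True)
        transitive_reduce(g)
        us = assemble_unitigs(g, dict(reads), stranded=True)
        assert len(us) == 1
        assert us[0].seq == t[:1700]  # the span the three reads tile

    def test_y_fork_three_unitigs(self, rnd):
        shared, alt1, alt2 = rnd(600, 41), rnd(600, 42), rnd(600, 43)
        iso1, iso2 = shared + alt1, shared + alt2
        reads = [("a0", iso1[0:500]), ("a1", iso1[300:800]),
                 ("a2", iso1[600:1200]), ("b1", iso2[300:800]),
                 ("b2", iso2[600:1200])]
        ov = find_overlaps(reads, stranded=True)
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads},
                                stranded=True)
        transitive_reduce(g)
        us = assemble_unitigs(g, dict(reads), stranded=True)
        assert len(us) == 3
        # the fork vertex a0 stays alone; branches extend to the isoform ends
        lengths = sorted(len(u) for u in us)
        assert lengths == [500, 900, 900]

    def test_singleton_vertex(self, rnd):
        seq = rnd(700, 51)
        g = build_overlap_graph([], {"solo": 700}, stranded=True)
        us = assemble_unitigs(g, {"solo": seq}, stranded=True)
        assert len(us) == 1 and us[0].seq == seq

    def test_unstranded_emits_each_unitig_once(self, rnd):
        t, reads = chained_reads(rnd, n=3, seed=61)
        flipped = [(rid, revcomp(s)) if i == 1 else (rid, s)
                   for i, (rid, s) in enumerate(reads)]
        ov = find_overlaps(flipped, stranded=False)
        g = build_overlap_graph(ov, {r: len(s) for r, s in flipped},
                                stranded=False)
        transitive_reduce(g)
        us = assemble_unitigs(g, dict(flipped), stranded=False)
        assert len(us) == 1
        assert us[0].seq in (t[:1700], revcomp(t[:1700]))

    def test_vertex_partition(self, rnd):
        t, reads = chained_reads(rnd, n=5, seed=71)
        ov = find_overlaps(reads, stranded=True)
        g = build_overlap_graph(ov, {r: len(s) for r, s in reads},
                                stranded=True)
        transitive_reduce(g)
        us = assemble_unitigs(g, dict(reads), stranded=True)
        used = [rid for u in us for rid, _, _ in u.reads]
        assert sorted(used) == sorted(r for r, _ in reads)
        assert len(us) <= len(reads)
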