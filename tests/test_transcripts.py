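"""Unitig-graph annotation, binomial edge filtering and greedy extraction."""

import math

import networkx as nx
import numpy as np
import pytest

from strobeasm import (binomial_edge_filter, greedy_assemble_transcripts,
                       normalized_read_count, reorient_by_polya)
from strobeasm.overlap import MapAlignment
from strobeasm.transcripts import annotate_graph


def aln(read_id, unitig_id, ts, te, strand="+", ulen=1000):
    return MapAlignment(read_id, te - ts, 0, te - ts, strand, unitig_id,
                        ulen, ts, te, 0.99, 0, f"{te - ts}=")


class TestNormalizedCount:
    def test_simple_ratio(self):
        alns = [aln(f"r{i}", "u", 0, 500) for i in range(10)]
        assert normalized_read_count(1000, alns) == pytest.approx(5.0)

    def test_no_alignments_zero(self):
        assert normalized_read_count(1000, []) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            normalized_read_count(0, [])

    def test_straddling_read_split_proportionally(self):
        g = nx.DiGraph()
        g.add_node(("A", 0), length=1000)
        g.add_node(("B", 0), length=1000)
        g.add_edge(("A", 0), ("B", 0), splice_from=0, ext=1000)
        alns = [aln("r", "A", 200, 1000), aln("r", "B", 0, 200)]
        annotate_graph(g, alns)
        assert g.nodes[("A", 0)]["count"] == pytest.approx(0.8)
        assert g.nodes[("B", 0)]["count"] == pytest.approx(0.2)
        assert g.edges[("A", 0), ("B", 0)]["support"] == 1


def exact_binom_cdf(s, n, p):
    return sum(math.comb(n, i) * p**i * (1 - p)**(n - i)
               for i in range(s + 1))


class TestBinomialFilter:
    def _graph(self, count_u, count_v, support):
        g = nx.DiGraph()
        g.add_node("u", length=1000, count=count_u)
        g.add_node("v", length=1000, count=count_v)
        g.add_edge("u", "v", support=support, splice_from=0, ext=1)
        return g

    def test_starved_edge_removed(self):
        g = self._graph(20.0, 20.0, 1)
        assert exact_binom_cdf(1, 20, 0.5) < 0.05
        binomial_edge_filter(g)
        assert g.number_of_edges() == 0

    def test_small_min_count_keeps_edge(self):
        g = self._graph(4.0, 400.0, 2)
        assert exact_binom_cdf(2, 4, 0.5) == pytest.approx(11 / 16)
        binomial_edge_filter(g)
        assert g.number_of_edges() == 1

    def test_evidence_floor(self):
        g = self._graph(2.0, 2.0, 0)
        binomial_edge_filter(g)
        assert g.number_of_edges() == 1

    @pytest.mark.parametrize("p", [0.25, 0.5])
    def test_matches_exact_enumeration(self, p):
        # every (n <= 20, s <= n) decision agrees with the closed-form CDF
        for n in range(3, 21):
            for s in range(0, n + 1):
                g = self._graph(float(n), float(n), s)
                binomial_edge_filter(g, alpha=0.05, spanning_prob=p)
                removed = g.number_of_edges() == 0
                assert removed == (exact_binom_cdf(s, n, p) < 0.05), (n, s, p)


class TestReorient:
    def _pair(self):
        g = nx.DiGraph()
        for name in ("A", "B"):
            for o in (0, 1):
                g.add_node((name, o), length=1000, count=5.0)
        # A 3' joins the flipped B (antisense-style join) and its mirror
        g.add_edge(("A", 0), ("B", 1), splice_from=400, ext=600, support=3)
        g.add_edge(("B", 0), ("A", 1), splice_from=400, ext=600, support=3)
        return g

    def test_majority_fixes_orientation(self):
        g = self._pair()
        reorient_by_polya(g, {"A": ["+", "+", "+", "-", "-"]})
        # orientation 0 preferred: its edges survive, the mirror's vanish
        assert g.has_edge(("A", 0), ("B", 1))
        assert not g.has_edge(("B", 0), ("A", 1))

    def test_antisense_join_fully_removed(self):
        g = self._pair()
        reorient_by_polya(g, {"A": ["+"] * 5, "B": ["+"] * 5})
        # both unitigs fixed forward: every edge touching an anti-preferred
        # orientation is gone, disconnecting the two genes
        assert g.number_of_edges() == 0


def linear_graph(counts, lengths=None, seqs_seed=0):
    g = nx.DiGraph()
    rng = np.random.default_rng(seqs_seed)
    seqs = {}
    names = [f"u{i}" for i in range(len(counts))]
    for name, c in zip(names, counts):
        L = 600
        g.add_node((name, 0), length=L, count=float(c))
        seqs[name] = "".join("ACGT"[b] for b in rng.integers(0, 4, L))
    for a, b in zip(names, names[1:]):
        g.add_edge((a, 0), (b, 0), splice_from=200, ext=400, support=3)
    return g, seqs


class TestGreedy:
    def test_linear_path_single_transcript(self):
        g, seqs = linear_graph([9, 8, 7])
        ts = greedy_assemble_transcripts(g, seqs)
        assert len(ts) == 1
        assert [v[0] for v in ts[0].path] == ["u0", "u1", "u2"]
        assert ts[0].path_min_count == 7

    def test_shared_unitig_two_isoforms(self):
        g = nx.DiGraph()
        rng = np.random.default_rng(1)
        seqs = {}
        for name, c in [("A1", 6.0), ("B1", 6.0), ("A2", 4.0),
                        ("B2", 4.0), ("M", 10.0)]:
            g.add_node((name, 0), length=500, count=c)
            seqs[name] = "".join("ACGT"[b] for b in rng.integers(0, 4, 500))
        for u, v in [("A1", "M"), ("M", "B1"), ("A2", "M"), ("M", "B2")]:
            g.add_edge((u, 0), (v, 0), splice_from=100, ext=400, support=4)
        ts = greedy_assemble_transcripts(g, seqs)
        paths = [[v[0] for v in t.path] for t in ts]
        assert ["A1", "M", "B1"] in paths
        assert ["A2", "M", "B2"] in paths
        mins = {tuple(p): t.path_min_count for p, t in zip(paths, ts)}
        assert mins[("A1", "M", "B1")] == 6.0
        assert mins[("A2", "M", "B2")] == 4.0

    def test_cycle_terminates(self):
        g, seqs = linear_graph([5, 5, 5])
        g.add_edge(("u2", 0), ("u0", 0), splice_from=200, ext=400, support=3)
        ts = greedy_assemble_transcripts(g, seqs)
        assert len(ts) == 1
        assert len(ts[0].path) == 3  # stops on revisit, no infinite loop

    def test_zero_count_seed_not_emitted(self):
        g, seqs = linear_graph([0, 0])
        assert greedy_assemble_transcripts(g, seqs) == []

    def test_conservation_of_counts(self):
        g, seqs = linear_graph([9, 4, 7, 2, 8])
        total = sum(g.nodes[v]["count"] for v in g.nodes)
        ts = greedy_assemble_transcripts(g, seqs)
        assert sum(t.path_min_count for t in ts) <= total

    def test_splice_concatenation(self):
        g, seqs = linear_graph([3, 3])
        ts = greedy_assemble_transcripts(g, seqs)
        expected = seqs["u0"] + seqs["u1"][200:]
        assert ts[0].seq == expected
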