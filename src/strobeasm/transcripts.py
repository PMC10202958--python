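"""Stage 6 — transcript extraction from the polished-unitig overlap graph.

Polished unitigs are overlapped and annotated with (i) length-normalized
read counts (aligned bases / unitig length) and (ii) per-edge spanning-read
support.  Edges whose support is significantly below what the incident
unitigs' counts predict are removed by an exact one-sided binomial test —
these are typically false overlaps between transcripts of very different
expression.  For unstranded data, unitigs are reoriented by their poly(A)
read alignments and inconsistent edges dropped.  Transcripts are then read
off by greedy bidirectional extension from high-count seeds, decrementing
counts by each path's minimum so shared unitigs (shared exons) can serve
several isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
from scipy.stats import binom

from .bloom import revcomp
from .overlap import MapAlignment, find_overlaps
from .unitig import (HEAD_T, NONE, PolyASignal, build_overlap_graph,
                     transitive_reduce)


@dataclass
class Transcript:
    id: str
    seq: str
    path: list  # (unitig_id, orient)
    path_min_count: float

    def __len__(self):
        return len(self.seq)


def normalized_read_count(unitig_len: int,
                          alignments: Sequence[MapAlignment]) -> float:
    """Aligned bases on the unitig divided by its length."""
    if unitig_len <= 0:
        raise ValueError("zero-length unitig")
    return sum(a.aligned_bases for a in alignments) / unitig_len


def annotate_graph(g: nx.DiGraph,
                   read_alignments: Sequence[MapAlignment]) -> nx.DiGraph:
    """Attach normalized counts to vertices and spanning support to edges.

    A read supports edge (u, v) when it has filtered alignments to both
    incident unitigs — the signature of a read spanning the overlap.
    """
    by_unitig: dict[str, list[MapAlignment]] = {}
    reads_of: dict[str, set[str]] = {}
    for a in read_alignments:
        by_unitig.setdefault(a.target_id, []).append(a)
        reads_of.setdefault(a.target_id, set()).add(a.query_id)
    for node in g.nodes:
        uid = node[0]
        count = normalized_read_count(g.nodes[node]["length"],
                                      by_unitig.get(uid, []))
        g.nodes[node]["count"] = count
    for u, v in g.edges:
        shared = reads_of.get(u[0], set()) & reads_of.get(v[0], set())
        g.edges[u, v]["support"] = len(shared)
    return g


def binomial_edge_filter(g: nx.DiGraph, alpha: float = 0.05,
                         spanning_prob: float = 0.5,
                         min_evidence: int = 3) -> nx.DiGraph:
    """Drop edges whose spanning support is significantly too low.

    For edge (u, v) with support s and n = round(min(count_u, count_v)),
    the edge is removed when P(X <= s | n, spanning_prob) < alpha.  Edges
    with n < min_evidence are kept — not enough reads to judge.
    """
    drop = []
    for u, v, data in g.edges(data=True):
        n = round(min(g.nodes[u]["count"], g.nodes[v]["count"]))
        if n < min_evidence:
            continue
        s = data["support"]
        if binom.cdf(s, n, spanning_prob) < alpha:
            drop.append((u, v))
    g.remove_edges_from(drop)
    return g


def reorient_by_polya(g: nx.DiGraph,
                      polya_alignments: Mapping[str, list[str]]) -> nx.DiGraph:
    """Fix unitig orientations from poly(A)-read alignment strands.

    ``polya_alignments`` maps unitig id → list of alignment strands
    ('+'/'-') of poly(A)-tail reads on it.  Majority decides the
    orientation that puts tails at the unitig 3' end; the disallowed
    orientation's vertex loses all its edges, so joins consistent only
    with the anti-preferred orientations of two oriented unitigs vanish.
    """
    preferred: dict[str, int] = {}
    for uid, strands in polya_alignments.items():
        if not strands:
            continue
        fwd = sum(1 for s in strands if s == "+")
        preferred[uid] = 0 if fwd * 2 >= len(strands) else 1
    drop = []
    for node in g.nodes:
        uid, o = node
        if uid in preferred and o != preferred[uid]:
            drop.extend((node, v) for v in g.successors(node))
            drop.extend((u, node) for u in g.predecessors(node))
    g.remove_edges_from(drop)
    return g


def _splice_path(path: list, g: nx.DiGraph,
                 sequences: Mapping[str, str]) -> str:
    rid0, o0 = path[0]
    seq0 = sequences[rid0] if o0 == 0 else revcomp(sequences[rid0])
    pieces = [seq0]
    for a, b in zip(path, path[1:]):
        data = g.edges[a, b]
        rid, o = b
        s = sequences[rid] if o == 0 else revcomp(sequences[rid])
        sf = min(data["splice_from"], len(s))
        pieces.append(s[sf:])
    return "".join(pieces)


def greedy_assemble_transcripts(g: nx.DiGraph,
                                sequences: Mapping[str, str],
                                stranded: bool = True,
                                prefix: str = "transcript") -> list[Transcript]:
    """Greedy bidirectional path extraction, highest-count seeds first.

    Seeds are visited in descending count (ties: longer unitig, then id);
    a vertex that already served on a path cannot seed again.  Extension
    always takes the neighbour with the highest current count and stops at
    a dead-end, a cycle (revisit within the path), or a zero-count vertex.
    After emitting a path, every vertex on it is decremented by the path
    minimum and flagged.
    """
    counts = {v: float(g.nodes[v]["count"]) for v in g.nodes}
    flagged: set = set()

    def seed_key(v):
        return (-counts[v], -g.nodes[v]["length"], v)

    def best_neighbor(candidates, path_set):
        usable = [c for c in candidates if c not in path_set and counts[c] > 0]
        if not usable:
            return None
        usable.sort(key=lambda c: (-counts[c], c))
        return usable[0]

    transcripts = []
    idx = 0
    emitted_seqs = set()
    for seedv in sorted(g.nodes, key=seed_key):
        if seedv in flagged:
            continue
        flagged.add(seedv)
        if counts[seedv] <= 0:
            continue
        path = [seedv]
        path_set = {seedv}
        # extend right
        cur = seedv
        while True:
            nxt = best_neighbor(list(g.successors(cur)), path_set)
            if nxt is None:
                break
            path.append(nxt)
            path_set.add(nxt)
            cur = nxt
        # extend left
        cur = seedv
        while True:
            prv = best_neighbor(list(g.predecessors(cur)), path_set)
            if prv is None:
                break
            path.insert(0, prv)
            path_set.add(prv)
            cur = prv
        min_count = min(counts[v] for v in path)
        seq = _splice_path(path, g, sequences)
        for v in path:
            counts[v] = max(0.0, counts[v] - min_count)
            flagged.add(v)
            if not stranded:
                mirror = (v[0], 1 - v[1])
                if mirror in g.nodes:
                    counts[mirror] = counts[v]
                    flagged.add(mirror)
        if not stranded:
            key = min(seq, revcomp(seq))
            if key in emitted_seqs:
                continue
            emitted_seqs.add(key)
        transcripts.append(Transcript(f"{prefix}{idx}", seq, list(path), min_count))
        idx += 1
    return transcripts


def assemble_transcripts(polished: Sequence[tuple[str, str]],
                         read_alignments: Sequence[MapAlignment],
                         polya_signals: Optional[Mapping[str, PolyASignal]] = None,
                         stranded: bool = True,
                         min_overlap: int = 150,
                         alpha: float = 0.05,
                         spanning_prob: float = 0.5,
                         fuzz: int = 10) -> list[Transcript]:
    """Full stage 6: overlap unitigs, annotate, filter, orient, extract."""
    sequences = dict(polished)
    lengths = {uid: len(s) for uid, s in polished}
    overlaps = find_overlaps(list(polished), min_overlap=min_overlap,
                             stranded=stranded)
    g = build_overlap_graph(overlaps, lengths, stranded=stranded)
    g = transitive_reduce(g, fuzz=fuzz)
    g = annotate_graph(g, read_alignments)
    g = binomial_edge_filter(g, alpha=alpha, spanning_prob=spanning_prob)
    if not stranded and polya_signals:
        # strands of poly(A)-read alignments per unitig
        polya_aln: dict[str, list[str]] = {}
        for a in read_alignments:
            sig = polya_signals.get(a.query_id)
            if sig is None or sig.kind == NONE:
                continue
            # a TAIL_A read aligned '+' puts the tail at the unitig 3' end;
            # a HEAD_T read is the antisense image, so flip its strand vote
            strand = a.strand
            if sig.kind == HEAD_T:
                strand = "+" if strand == "-" else "-"
            polya_aln.setdefault(a.target_id, []).append(strand)
        g = reorient_by_polya(g, polya_aln)
    return greedy_assemble_transcripts(g, sequences, stranded=stranded)
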