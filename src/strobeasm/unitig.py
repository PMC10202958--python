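"""Stage 4 — overlap-graph unitig assembly.

Trimmed read segments are overlapped all-vs-all and arranged in a string
graph: vertices are (read, orientation) pairs (forward-only when the input
is strand-specific), edges are dovetail overlaps.  For unstranded (cDNA)
input the graph is strand-symmetric, and poly(A)-tail / poly(T)-head
signals prune edges that would extend past a transcript's 3' end or join
antisense-overlapping genes.  Transitive edges are removed (Myers-style,
with small coordinate fuzz for residual indels), and unitigs are read off
maximal unambiguous paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx

from .bloom import revcomp
from .overlap import (DOVETAIL_QT, DOVETAIL_TQ, OverlapRecord,
                      classify_overlap)

TAIL_A = "TAIL_A"
HEAD_T = "HEAD_T"
NONE = "NONE"


@dataclass(frozen=True)
class PolyASignal:
    read_id: str
    kind: str  # TAIL_A | HEAD_T | NONE
    tail_length: int = 0


def _best_tail(seq: str, base: str, window: int, min_tail: int,
               min_purity: float) -> int:
    """Longest qualifying 3'-terminal run of ``base``; 0 if none.

    Examines suffixes starting within the terminal ``window``; a suffix
    qualifies when it holds >= min_tail copies of ``base`` at >= min_purity.
    A qualifying run is extended leftward through pure ``base`` positions so
    tails longer than the window are fully measured.
    """
    n = len(seq)
    best_p, best_count = -1, 0
    for p in range(max(0, n - window), n):
        seg = seq[p:]
        cnt = seg.count(base)
        if cnt >= min_tail and cnt / len(seg) >= min_purity and cnt > best_count:
            best_p, best_count = p, cnt
    if best_p < 0:
        return 0
    p = best_p
    while p > 0 and seq[p - 1] == base:
        p -= 1
        best_count += 1
    return best_count


def detect_polya(read: str, min_tail: int = 10, window: int = 20,
                 min_purity: float = 0.9, read_id: str = "") -> PolyASignal:
    """Detect a poly(A) tail (3') or poly(T) head (5'); tail takes precedence."""
    tail = _best_tail(read, "A", window, min_tail, min_purity)
    if tail:
        return PolyASignal(read_id, TAIL_A, tail)
    head = _best_tail(read[::-1], "T", window, min_tail, min_purity)
    if head:
        return PolyASignal(read_id, HEAD_T, head)
    return PolyASignal(read_id, NONE, 0)


def _oriented_interval(s: int, e: int, length: int, orient: int) -> tuple[int, int]:
    return (s, e) if orient == 0 else (length - e, length - s)


def _edge_endpoints(rec: OverlapRecord, cls: str) -> Optional[tuple]:
    """Dovetail edge as ((id, orient) source, (id, orient) dest).

    Orientation 0 is the sequence as given, 1 its reverse complement; the
    edge runs from the read whose (oriented) suffix matches the other's
    (oriented) prefix.
    """
    flip = 1 if rec.strand == "-" else 0
    if cls == DOVETAIL_QT:
        return (rec.query_id, 0), (rec.target_id, flip)
    if cls == DOVETAIL_TQ:
        return (rec.target_id, flip), (rec.query_id, 0)
    return None


def build_overlap_graph(overlaps: Sequence[OverlapRecord],
                        lengths: Mapping[str, int],
                        stranded: bool,
                        max_overhang: int = 25) -> nx.DiGraph:
    """Dovetail-only string graph over (read, orientation) vertices.

    Edge attributes: ``splice_from`` (oriented coordinate on the destination
    where its novel suffix begins) and ``ext`` (bases that suffix adds).
    Unstranded mode adds every vertex and edge in both orientations.
    """
    g = nx.DiGraph()
    orients = (0,) if stranded else (0, 1)
    for rid in lengths:
        for o in orients:
            g.add_node((rid, o), length=lengths[rid])
    for rec in overlaps:
        if rec.query_id not in lengths or rec.target_id not in lengths:
            warnings.warn(f"overlap references removed read: "
                          f"{rec.query_id}/{rec.target_id}")
            continue
        cls = classify_overlap(rec, max_overhang)
        ends = _edge_endpoints(rec, cls)
        if ends is None:
            continue
        (uid, uo), (vid, vo) = ends
        if stranded and (rec.strand == "-" or uo or vo):
            continue
        for mirror in (False, True):
            if mirror:
                if stranded:
                    break
                su, so_u = vid, 1 - vo
                sv, so_v = uid, 1 - uo
            else:
                su, so_u, sv, so_v = uid, uo, vid, vo
            # interval of the overlap on the destination, in its orientation
            if sv == rec.query_id:
                s, e = rec.query_start, rec.query_end
            else:
                s, e = rec.target_start, rec.target_end
            vs, ve = _oriented_interval(s, e, lengths[sv], so_v)
            ext = lengths[sv] - ve
            if ext <= 0:
                continue  # destination adds nothing (containment-like)
            g.add_edge((su, so_u), (sv, so_v), splice_from=ve, ext=ext,
                       overlap_len=ve - vs)
    return g


def signal_in_orientation(kind: str, orient: int) -> str:
    if kind == NONE:
        return NONE
    if orient == 0:
        return kind
    return TAIL_A if kind == HEAD_T else HEAD_T


def prune_by_polya(g: nx.DiGraph,
                   signals: Mapping[str, PolyASignal]) -> nx.DiGraph:
    """Remove edges extending past poly(A) 3' ends / into poly(T) 5' heads.

    In the orientation where a read shows a poly(A) tail nothing may extend
    its 3' end (outgoing edges dropped); in the opposite orientation the
    read starts with a poly(T) head and nothing may extend its 5' end
    (incoming edges dropped).  Applied over both orientations this also
    disconnects head-to-head joins between antisense overlapping genes.
    """
    to_drop = []
    for node in g.nodes:
        rid, o = node
        sig = signals.get(rid)
        if sig is None or sig.kind == NONE:
            continue
        eff = signal_in_orientation(sig.kind, o)
        if eff == TAIL_A:
            to_drop.extend((node, v) for v in g.successors(node))
        elif eff == HEAD_T:
            to_drop.extend((u, node) for u in g.predecessors(node))
    g.remove_edges_from(to_drop)
    return g


def transitive_reduce(g: nx.DiGraph, fuzz: int = 10) -> nx.DiGraph:
    """Remove edges implied by a consistent two-step path (single pass).

    Edge u→w is transitive when edges u→v and v→w exist with
    ext(u→v) + ext(v→w) within ``fuzz`` of ext(u→w).  The check runs
    against the original edge set, so removal order cannot matter.
    """
    redundant = []
    for u, w, data in g.edges(data=True):
        e_uw = data["ext"]
        for v in g.successors(u):
            if v == w or not g.has_edge(v, w):
                continue
            e_uv = g.edges[u, v]["ext"]
            e_vw = g.edges[v, w]["ext"]
            if abs(e_uv + e_vw - e_uw) <= fuzz:
                redundant.append((u, w))
                break
    g.remove_edges_from(redundant)
    return g


def write_gfa(g: nx.DiGraph, sequences: Mapping[str, str], path) -> None:
    """Export a (reduced) overlap graph as GFA1 S/L lines for inspection."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for rid in sorted({node[0] for node in g.nodes}):
            fh.write(f"S\t{rid}\t{sequences[rid]}\n")
        for (uid, uo), (vid, vo), data in g.edges(data=True):
            if not (uo == 0 or (uid, 1 - uo) not in g.nodes):
                # in strand-symmetric graphs, emit each link once (from the
                # forward orientation of the source)
                if uo == 1:
                    continue
            ou = "+-"[uo]
            ov = "+-"[vo]
            fh.write(f"L\t{uid}\t{ou}\t{vid}\t{ov}\t{data['overlap_len']}M\n")


@dataclass
class Unitig:
    id: str
    seq: str
    reads: list  # (read_id, orient, offset in unitig)

    def __len__(self):
        return len(self.seq)


def _oriented_seq(seq: str, orient: int) -> str:
    return seq if orient == 0 else revcomp(seq)


def _path_nodes(g: nx.DiGraph) -> list[list]:
    """Maximal unambiguous paths partitioning the vertex set.

    A vertex starts a path unless it has exactly one predecessor whose
    out-degree is one (then it is reached by walking).  Pure cycles, where
    every vertex is interior, are broken at their smallest vertex.
    """
    def is_start(v):
        if g.in_degree(v) != 1:
            return True
        pred = next(iter(g.predecessors(v)))
        return g.out_degree(pred) != 1

    paths = []
    seen = set()

    def walk(v):
        path = [v]
        seen.add(v)
        cur = v
        while g.out_degree(cur) == 1:
            nxt = next(iter(g.successors(cur)))
            if g.in_degree(nxt) != 1 or nxt in seen:
                break
            path.append(nxt)
            seen.add(nxt)
            cur = nxt
        return path

    for v in sorted(g.nodes):
        if v in seen or not is_start(v):
            continue
        paths.append(walk(v))
    for v in sorted(g.nodes):  # leftover pure cycles
        if v not in seen:
            paths.append(walk(v))
    return paths


def assemble_unitigs(g: nx.DiGraph, sequences: Mapping[str, str],
                     signals: Optional[Mapping[str, PolyASignal]] = None,
                     stranded: bool = True,
                     prefix: str = "unitig") -> list[Unitig]:
    """Merge reads along unambiguous paths into unitigs.

    The first read is taken verbatim (in its path orientation); every
    successor contributes the suffix beyond its overlap (``splice_from``).
    In unstranded mode each unitig and its mirror collapse to one record in
    canonical orientation: poly(A) tail at the 3' end when known, otherwise
    the lexicographic minimum of sequence and reverse complement.
    """
    signals = signals or {}
    unitigs = []
    seen_mirror = set()
    idx = 0
    for path in _path_nodes(g):
        mirror_key = frozenset((rid, 1 - o) for rid, o in path)
        this_key = frozenset(path)
        if not stranded:
            if mirror_key in seen_mirror and mirror_key != this_key:
                continue
            seen_mirror.add(this_key)
        pieces = []
        reads = []
        offset = 0
        ok = True
        rid0, o0 = path[0]
        pieces.append(_oriented_seq(sequences[rid0], o0))
        reads.append((rid0, o0, 0))
        offset = len(pieces[0])
        for a, b in zip(path, path[1:]):
            data = g.edges[a, b]
            rid, o = b
            seq = _oriented_seq(sequences[rid], o)
            sf = data["splice_from"]
            if sf >= len(seq):
                warnings.warn(f"inconsistent overlap coordinates on edge {a}->{b}")
                ok = False
                break
            reads.append((rid, o, offset - sf))
            pieces.append(seq[sf:])
            offset += len(seq) - sf
        seq = "".join(pieces)
        if not stranded:
            # canonical orientation
            kinds = [signal_in_orientation(signals[rid].kind, o)
                     for rid, o in path if rid in signals and signals[rid].kind != NONE]
            if kinds:
                n_tail = sum(1 for kk in kinds if kk == TAIL_A)
                if n_tail * 2 < len(kinds):
                    seq = revcomp(seq)
            elif revcomp(seq) < seq:
                seq = revcomp(seq)
        unitigs.append(Unitig(f"{prefix}{idx}", seq, reads))
        idx += 1
    return unitigs
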