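"""All-vs-all read overlapping: minimizer seeding, colinear chaining, PAF I/O.

The assembler's overlap stages need dovetail/containment overlaps between
reads (and later between unitigs).  This module provides a self-contained
overlapper — canonical minimizer seeds, per-pair colinear chaining, exact
end extension — plus PAF import/export so an external aligner's all-vs-all
output can be substituted verbatim.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .bloom import kmer_array, revcomp, splitmix64

DOVETAIL_QT = "DOVETAIL_QT"  # query suffix overlaps target prefix
DOVETAIL_TQ = "DOVETAIL_TQ"  # target suffix overlaps query prefix
CONTAINS = "CONTAINS"        # target contained in query
CONTAINED = "CONTAINED"      # query contained in target
INTERNAL = "INTERNAL"


@dataclass(frozen=True)
class OverlapRecord:
    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matching_bases: int
    block_len: int
    mapq: int = 255
    tags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.query_id == self.target_id:
            raise ValueError("self-overlap record")
        for s, e, ln in ((self.query_start, self.query_end, self.query_len),
                         (self.target_start, self.target_end, self.target_len)):
            if not (0 <= s < e <= ln):
                raise ValueError("invalid overlap coordinates")

    @property
    def identity_estimate(self) -> float:
        return self.matching_bases / self.block_len if self.block_len else 0.0

    def interval_on(self, seq_id: str) -> tuple[int, int]:
        if seq_id == self.query_id:
            return self.query_start, self.query_end
        if seq_id == self.target_id:
            return self.target_start, self.target_end
        raise KeyError(seq_id)

    def flipped(self) -> "OverlapRecord":
        """Same overlap with query/target roles exchanged."""
        return OverlapRecord(self.target_id, self.target_len, self.target_start,
                             self.target_end, self.strand, self.query_id,
                             self.query_len, self.query_start, self.query_end,
                             self.matching_bases, self.block_len, self.mapq,
                             self.tags)


# -- minimizer seeds ---------------------------------------------------------


def minimizers(seq: str, k: int = 15, w: int = 10,
               seed: int = 7) -> list[tuple[int, int, int]]:
    """(position, hash, strand) canonical minimizers of a sequence.

    strand 0 means the forward k-mer is the canonical one, 1 the reverse.
    """
    fwd, valid = kmer_array(seq, k)
    if fwd.size == 0:
        return []
    rc_all, _ = kmer_array(revcomp(seq), k)
    rc = rc_all[::-1]
    canon = np.minimum(fwd, rc)
    strand = (rc < fwd).astype(np.int8)
    h = splitmix64(canon ^ np.uint64(seed))
    h = np.where(valid, h, np.uint64(0xFFFFFFFFFFFFFFFF))
    n = h.size
    if n <= w:
        picks = {int(h.argmin())}
    else:
        win = np.lib.stride_tricks.sliding_window_view(h, w)
        arg = win.argmin(axis=1) + np.arange(win.shape[0])
        picks = set(arg.tolist())
    out = []
    for p in sorted(picks):
        if valid[p]:
            out.append((p, int(h[p]), int(strand[p])))
    return out


def _chain(matches: list[tuple[int, int]], max_gap: int, k: int,
           max_chains: int = 1, min_seeds: int = 3) -> list[list[tuple[int, int]]]:
    """Colinear chains of (qpos, tpos) matches (simple banded O(m^2) DP).

    Returns up to ``max_chains`` chains; after each chain its query span is
    masked so secondary chains (split alignments) occupy distinct segments.
    """
    pool = sorted(set(matches))
    chains: list[list[tuple[int, int]]] = []
    while pool and len(chains) < max_chains:
        m = len(pool)
        score = [1] * m
        prev = [-1] * m
        for i in range(m):
            qi, ti = pool[i]
            for j in range(max(0, i - 64), i):  # band limits blowup
                qj, tj = pool[j]
                dq, dt = qi - qj, ti - tj
                if dq <= 0 or dt <= 0:
                    continue
                if dq > max_gap + k or dt > max_gap + k:
                    continue
                if abs(dq - dt) > max_gap:
                    continue
                if score[j] + 1 > score[i]:
                    score[i] = score[j] + 1
                    prev[i] = j
        best = int(np.argmax(score))
        chain = []
        i = best
        while i != -1:
            chain.append(pool[i])
            i = prev[i]
        chain.reverse()
        if len(chain) < min_seeds:
            break
        chains.append(chain)
        qlo, qhi = chain[0][0], chain[-1][0] + k
        pool = [mt for mt in pool if mt[0] + k <= qlo or mt[0] >= qhi]
    return chains


def _extend_ends(qseq: str, tseq: str, qs: int, qe: int, ts: int, te: int,
                 strand: str) -> tuple[int, int, int, int, int]:
    """Greedy exact extension of a chain's ends; returns coords + extra matches."""
    extra = 0
    if strand == "+":
        while qs > 0 and ts > 0 and qseq[qs - 1] == tseq[ts - 1]:
            qs -= 1; ts -= 1; extra += 1
        while qe < len(qseq) and te < len(tseq) and qseq[qe] == tseq[te]:
            qe += 1; te += 1; extra += 1
    else:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        # query forward start pairs with target end
        while qs > 0 and te < len(tseq) and comp.get(qseq[qs - 1]) == tseq[te]:
            qs -= 1; te += 1; extra += 1
        while qe < len(qseq) and ts > 0 and comp.get(qseq[qe]) == tseq[ts - 1]:
            qe += 1; ts -= 1; extra += 1
    return qs, qe, ts, te, extra


def find_overlaps(sequences: Sequence[tuple[str, str]], min_overlap: int = 150,
                  stranded: bool = False, k: int = 15, w: int = 10,
                  max_gap: int = 100, min_seeds: int = 3,
                  seed: int = 7) -> list[OverlapRecord]:
    """All-vs-all overlaps among (id, sequence) pairs.

    Each unordered pair is reported at most once per strand orientation,
    with the earlier input sequence as query.  In stranded mode,
    minus-strand overlaps are suppressed.
    """
    ids = [sid for sid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = {sid: s for sid, s in sequences}
    index: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    mins = []
    for idx, (sid, s) in enumerate(sequences):
        mm = minimizers(s, k=k, w=w, seed=seed)
        mins.append(mm)
        for pos, h, st in mm:
            index[h].append((idx, pos, st))
    # collect per-pair, per-relative-strand seed matches
    pair_matches: dict[tuple[int, int, str], list[tuple[int, int]]] = defaultdict(list)
    for h, occ in index.items():
        if len(occ) < 2 or len(occ) > 64:  # skip overly repetitive seeds
            continue
        for a in range(len(occ)):
            ia, pa, sa = occ[a]
            for b in range(a + 1, len(occ)):
                ib, pb, sb = occ[b]
                if ia == ib:
                    continue
                (iq, pq, sq), (it, pt, st) = ((ia, pa, sa), (ib, pb, sb)) \
                    if ia < ib else ((ib, pb, sb), (ia, pa, sa))
                rel = "+" if sq == st else "-"
                if stranded and rel == "-":
                    continue
                tlen = len(seqs[ids[it]])
                tpos = pt if rel == "+" else tlen - (pt + k)
                pair_matches[(iq, it, rel)].append((pq, tpos))
    records = []
    for (iq, it, rel), matches in sorted(pair_matches.items()):
        if len(matches) < min_seeds:
            continue
        chains = _chain(matches, max_gap, k, max_chains=1, min_seeds=min_seeds)
        for chain in chains:
            if len(chain) < min_seeds:
                continue
            qid, tid = ids[iq], ids[it]
            qseq, tseq = seqs[qid], seqs[tid]
            qs, qe = chain[0][0], chain[-1][0] + k
            if rel == "+":
                ts, te = chain[0][1], chain[-1][1] + k
            else:
                # undo the reversed-coordinate transform
                te = len(tseq) - chain[0][1]
                ts = len(tseq) - (chain[-1][1] + k)
            # matched bases: union of seed intervals on the query
            matched = 0
            last = -1
            for qp, _ in chain:
                s0 = max(qp, last)
                matched += max(0, qp + k - s0)
                last = max(last, qp + k)
            qs, qe, ts, te, extra = _extend_ends(qseq, tseq, qs, qe, ts, te, rel)
            matched += extra
            block = max(qe - qs, te - ts)
            if min(qe - qs, te - ts) < min_overlap:
                continue
            records.append(OverlapRecord(qid, len(qseq), qs, qe, rel, tid,
                                         len(tseq), ts, te,
                                         min(matched, block), block))
    return records


def classify_overlap(rec: OverlapRecord, max_overhang: int = 25) -> str:
    """String-graph classification by unaligned overhang lengths."""
    q_left = rec.query_start
    q_right = rec.query_len - rec.query_end
    if rec.strand == "+":
        t_left = rec.target_start
        t_right = rec.target_len - rec.target_end
    else:
        t_left = rec.target_len - rec.target_end
        t_right = rec.target_start
    o = max_overhang
    if q_left <= o and q_right <= o:
        return CONTAINED
    if t_left <= o and t_right <= o:
        return CONTAINS
    if q_right <= o and t_left <= o:
        return DOVETAIL_QT
    if q_left <= o and t_right <= o:
        return DOVETAIL_TQ
    return INTERNAL


# -- query-to-target mapping with base-level refinement ----------------------


@dataclass(frozen=True)
class MapAlignment:
    """A refined query→target alignment segment (for polishing/evaluation)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    identity: float
    largest_indel: int
    cigar: str  # extended ops over (oriented query segment, target segment)

    @property
    def aligned_bases(self) -> int:
        return self.target_end - self.target_start


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(match_cols, total_cols, largest_indel) from an extended CIGAR."""
    import re

    match = total = largest = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n)
        total += n
        if op in "=M":
            match += n
        if op in "ID":
            largest = max(largest, n)
    return match, total, largest


def refine_alignment(qseg: str, tseg: str) -> tuple[float, int, str]:
    """Global-align two segments; returns (identity, largest_indel, cigar)."""
    import edlib

    res = edlib.align(qseg, tseg, mode="NW", task="path")
    cigar = res["cigar"] or ""
    match, total, largest = _cigar_stats(cigar)
    ident = match / total if total else 0.0
    return ident, largest, cigar


def map_queries(queries: Sequence[tuple[str, str]],
                targets: Sequence[tuple[str, str]],
                k: int = 15, w: int = 10, max_gap: int = 100,
                min_seeds: int = 3, min_span: int = 100,
                max_chains: int = 3, seed: int = 7) -> list[MapAlignment]:
    """Map each query onto the targets; base-level refinement with edlib.

    Unlike :func:`find_overlaps` this is asymmetric (reads onto unitigs,
    contigs onto reference transcripts) and may report several split
    segments per query/target pair.
    """
    index: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
    for tix, (tid, tseq) in enumerate(targets):
        for pos, h, st in minimizers(tseq, k=k, w=w, seed=seed):
            index[h].append((tix, pos, st))
    out = []
    for qid, qseq in queries:
        per_target: dict[tuple[int, str], list[tuple[int, int]]] = defaultdict(list)
        for qpos, h, qst in minimizers(qseq, k=k, w=w, seed=seed):
            occ = index.get(h)
            if not occ or len(occ) > 64:
                continue
            for tix, tpos, tst in occ:
                rel = "+" if qst == tst else "-"
                tlen = len(targets[tix][1])
                tp = tpos if rel == "+" else tlen - (tpos + k)
                per_target[(tix, rel)].append((qpos, tp))
        for (tix, rel), matches in sorted(per_target.items()):
            tid, tseq = targets[tix]
            for chain in _chain(matches, max_gap, k, max_chains=max_chains,
                                min_seeds=min_seeds):
                qs, qe = chain[0][0], chain[-1][0] + k
                if rel == "+":
                    ts, te = chain[0][1], chain[-1][1] + k
                else:
                    te = len(tseq) - chain[0][1]
                    ts = len(tseq) - (chain[-1][1] + k)
                qs, qe, ts, te, _ = _extend_ends(qseq, tseq, qs, qe, ts, te, rel)
                if min(qe - qs, te - ts) < min_span:
                    continue
                qseg = qseq[qs:qe] if rel == "+" else revcomp(qseq[qs:qe])
                ident, largest, cigar = refine_alignment(qseg, tseq[ts:te])
                # unit-cost alignment scatters long gaps into pieces; the
                # diagonal jumps of the seed chain recover structural indels
                diag_jump = max((abs((q2 - q1) - (t2 - t1))
                                 for (q1, t1), (q2, t2) in zip(chain, chain[1:])),
                                default=0)
                largest = max(largest, diag_jump)
                out.append(MapAlignment(qid, len(qseq), qs, qe, rel, tid,
                                        len(tseq), ts, te, ident, largest, cigar))
    return out


# -- PAF ---------------------------------------------------------------------


def write_paf(records: Iterable[OverlapRecord]) -> str:
    lines = []
    for r in records:
        cols = [r.query_id, r.query_len, r.query_start, r.query_end, r.strand,
                r.target_id, r.target_len, r.target_start, r.target_end,
                r.matching_bases, r.block_len, r.mapq, *r.tags]
        lines.append("\t".join(str(c) for c in cols))
    return "\n".join(lines) + ("\n" if lines else "")


def parse_paf(text: str) -> list[OverlapRecord]:
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 12:
            raise ValueError(f"PAF line {lineno}: expected >= 12 columns, got {len(cols)}")
        try:
            rec = OverlapRecord(
                query_id=cols[0], query_len=int(cols[1]),
                query_start=int(cols[2]), query_end=int(cols[3]),
                strand=cols[4], target_id=cols[5], target_len=int(cols[6]),
                target_start=int(cols[7]), target_end=int(cols[8]),
                matching_bases=int(cols[9]), block_len=int(cols[10]),
                mapq=int(cols[11]), tags=tuple(cols[12:]))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"PAF line {lineno}: {exc}") from exc
        if rec.strand not in "+-":
            raise ValueError(f"PAF line {lineno}: bad strand {rec.strand!r}")
        records.append(rec)
    return records


def read_paf(path) -> list[OverlapRecord]:
    with open(path) as fh:
        return parse_paf(fh.read())


def write_paf_file(records: Iterable[OverlapRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(write_paf(records))
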