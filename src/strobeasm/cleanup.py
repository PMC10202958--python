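"""Stage 3 — depth-based read trimming and chimera splitting.

After normalization, reads are overlapped all-vs-all; a region of a read is
sufficiently covered when it overlaps at least two other reads (depth >= 3
counting the read itself).  Under-covered head/tail regions are trimmed,
and internal under-covered valleys — the signature of chimeric (fused)
reads — split the read into separate segments.  Completely contained reads
are removed beforehand.  No bases are edited here: every output segment is
an exact substring of its input read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .overlap import OverlapRecord


@dataclass
class DepthProfile:
    read_id: str
    depth: np.ndarray  # per-base, self-inclusive (>= 1 everywhere)


def contained_ids(overlaps: Iterable[OverlapRecord],
                  max_overhang: int = 25) -> set[str]:
    """Ids of reads completely contained in another read.

    Near-identical reads contain each other; dropping both would lose the
    sequence entirely, so mutual containments keep the longer read (ties:
    the lexicographically smaller id survives).
    """
    gone: set[str] = set()
    o = max_overhang
    for rec in overlaps:
        ql, qr = rec.query_start, rec.query_len - rec.query_end
        if rec.strand == "+":
            tl, tr = rec.target_start, rec.target_len - rec.target_end
        else:
            tl, tr = rec.target_len - rec.target_end, rec.target_start
        q_cont = ql <= o and qr <= o
        t_cont = tl <= o and tr <= o
        if q_cont and t_cont:
            if (rec.query_len, rec.target_id) < (rec.target_len, rec.query_id):
                gone.add(rec.query_id)
            else:
                gone.add(rec.target_id)
        elif q_cont:
            gone.add(rec.query_id)
        elif t_cont:
            gone.add(rec.target_id)
    return gone


def compute_depth_profile(read_id: str, read_len: int,
                          overlaps: Iterable[OverlapRecord]) -> DepthProfile:
    """Per-base depth: 1 (the read itself) + covering overlap intervals."""
    diff = np.zeros(read_len + 1, dtype=np.int64)
    for rec in overlaps:
        if read_id not in (rec.query_id, rec.target_id):
            continue
        s, e = rec.interval_on(read_id)
        if not (0 <= s < e <= read_len):
            raise ValueError(f"overlap interval ({s},{e}) outside read of length {read_len}")
        diff[s] += 1
        diff[e] -= 1
    depth = np.cumsum(diff[:-1]) + 1
    return DepthProfile(read_id, depth)


def trim_split_read(read_id: str, seq: str, profile: DepthProfile,
                    min_depth: int = 3, min_segment: int = 200
                    ) -> list[tuple[str, str, tuple[int, int]]]:
    """Segments of the read with depth >= min_depth, at least min_segment nt.

    Returns (segment_id, sequence, (start, end)) triples; segment ids are
    suffixed _p0, _p1, ... in read coordinates order.
    """
    if profile.depth.size != len(seq):
        raise ValueError("profile length mismatch")
    ok = profile.depth >= min_depth
    segments = []
    i = 0
    n = len(seq)
    idx = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_segment:
                segments.append((f"{read_id}_p{idx}", seq[i:j], (i, j)))
                idx += 1
            i = j
        else:
            i += 1
    return segments


def trim_split_reads(reads: Sequence[tuple[str, str]],
                     overlaps: Sequence[OverlapRecord],
                     min_depth: int = 3, min_segment: int = 200,
                     max_overhang: int = 25
                     ) -> tuple[list[tuple[str, str]], dict[str, list[tuple[int, int]]]]:
    """Stage-3 driver: drop contained reads, trim/split the rest.

    Returns (segments, kept-interval log keyed by original read id).
    Contained reads are not emitted, but their overlaps still count as
    coverage evidence for the reads that contain them.
    """
    gone = contained_ids(overlaps, max_overhang)
    live = [(rid, seq) for rid, seq in reads if rid not in gone]
    live_ids = {rid for rid, _ in live}
    by_read: dict[str, list[OverlapRecord]] = {rid: [] for rid in live_ids}
    for rec in overlaps:
        if rec.query_id in by_read:
            by_read[rec.query_id].append(rec)
        if rec.target_id in by_read:
            by_read[rec.target_id].append(rec)
    segments = []
    log: dict[str, list[tuple[int, int]]] = {}
    for rid, seq in live:
        profile = compute_depth_profile(rid, len(seq), by_read[rid])
        segs = trim_split_read(rid, seq, profile, min_depth, min_segment)
        segments.extend((sid, s) for sid, s, _ in segs)
        log[rid] = [iv for _, _, iv in segs]
    return segments, log
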