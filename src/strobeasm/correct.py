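"""Stage 1 — alignment-free error correction of long reads.

Reads are split into fixed-length tiles; within each tile a multiplicity
threshold is chosen dynamically so that k-mers below it are "weak"
(potentially erroneous) and those at or above it are "solid".  Runs of weak
k-mers flanked by solid anchors are replaced by an alternative path of solid
k-mers found in the Bloom-filter de Bruijn graph, but only when that path
aligns to the original span at high identity (default 70%).  A second
iteration shifts the tiling by half a tile so errors straddling tile
boundaries get a chance to be repaired.  This stage is deliberately light:
residual errors are left for the alignment-based polishing stage.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from .bloom import KmerMultiplicityGraph

DISCARD = None  # sentinel result for reads dropped by the retention filter


@dataclass
class CorrectionConfig:
    k: int = 25
    tile_length: int = 500
    min_path_identity: float = 0.70
    max_iterations: int = 10  # safety cap; iteration stops at quiescence
    min_solid_fraction_keep: float = 0.1
    max_expanded_states: int = 64
    max_candidate_paths: int = 4

    def __post_init__(self):
        if not (0 < self.min_path_identity <= 1):
            raise ValueError("min_path_identity must be in (0, 1]")
        if self.tile_length <= self.k:
            raise ValueError("tile_length must exceed k")


def tile_read(read_length: int, tile_length: int, offset: int = 0) -> list[tuple[int, int]]:
    """Contiguous, non-overlapping tile coordinates covering the read.

    With a non-zero offset the leading partial tile [0, offset) is emitted so
    the tiling still covers the whole read.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    tiles = []
    if offset > 0:
        tiles.append((0, min(offset, read_length)))
    start = offset
    while start < read_length:
        tiles.append((start, min(start + tile_length, read_length)))
        start += tile_length
    return tiles


def dynamic_threshold(multiplicities) -> int:
    """Tile-local weak/solid multiplicity cutoff (k-mers < t are weak).

    Base rule t = max(2, ceil(q25/10)) scales with tile coverage; when the
    tile's multiplicity histogram has a valley below its median (the gap
    between the error mode near 1 and the coverage mode), the deepest such
    valley replaces the base value.  This is a reconstruction of the
    dynamic-threshold idea; see docs/methods.md.
    """
    mults = np.asarray(list(multiplicities), dtype=np.int64)
    if mults.size == 0:
        raise ValueError("empty multiplicity list")
    q25 = float(np.percentile(mults, 25))
    t = max(2, int(np.ceil(q25 / 10.0)))
    med = int(np.floor(np.median(mults)))
    if med >= 2:
        hist = np.bincount(mults, minlength=med + 2)
        best_v, best_count = None, None
        for v in range(2, med + 1):
            left = hist[v - 1]
            right = hist[v + 1] if v + 1 < hist.size else 0
            if hist[v] <= left and hist[v] <= right:
                if best_count is None or hist[v] < best_count:
                    best_v, best_count = v, hist[v]
        if best_v is not None:
            t = best_v
    return t


def _weak_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Anchored maximal runs of weak k-mer indices [a, b) within a segment.

    Only runs with a solid k-mer on both sides qualify; runs touching either
    segment end are skipped (no anchor to search from/to).
    """
    runs = []
    n = labels.size
    i = 0
    while i < n:
        if not labels[i]:  # weak
            j = i
            while j < n and not labels[j]:
                j += 1
            if i > 0 and j < n:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _solid_paths(graph: KmerMultiplicityGraph, start_kmer: str, goal_kmer: str,
                 threshold: int, max_len: int, config: CorrectionConfig) -> list[tuple[str, int]]:
    """Bounded best-first search for solid paths start→goal in the graph.

    Returns up to ``max_candidate_paths`` (sequence, min_multiplicity) pairs,
    where sequence spans start_kmer..goal_kmer inclusive.  Best-first by
    maximum of path-minimum multiplicity; deterministic tie-breaks.
    """
    k = graph.k
    found: list[tuple[str, int]] = []
    start_fwd, start_rc = graph.pack_state(start_kmer)
    goal_fwd, _ = graph.pack_state(goal_kmer)
    # heap entries: (-min_mult, len(seq), seq, fwd, rc); seq ends with the
    # current k-mer, tracked as packed ints for fast successor queries
    heap = [(-(1 << 30), k, start_kmer, start_fwd, start_rc)]
    expanded = 0
    while heap and expanded < config.max_expanded_states and \
            len(found) < config.max_candidate_paths:
        neg_mm, _, seq, fwd, rc = heapq.heappop(heap)
        expanded += 1
        for b, nf, nr, mult in graph.successor_states(fwd, rc):
            if mult < threshold:
                continue
            new_seq = seq + "ACGT"[b]
            if len(new_seq) > max_len:
                continue
            new_mm = min(-neg_mm, mult)
            if nf == goal_fwd:
                found.append((new_seq, new_mm))
            else:
                heapq.heappush(heap, (-new_mm, len(new_seq), new_seq, nf, nr))
    return found


def _identity(a: str, b: str) -> float:
    """Global-alignment identity (unit costs) between two sequences."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def correct_tile(segment: str, graph: KmerMultiplicityGraph,
                 config: CorrectionConfig,
                 threshold: Optional[int] = None) -> tuple[str, bool]:
    """Correct one tile; returns (possibly edited segment, modified?)."""
    k = config.k
    if len(segment) < k:
        return segment, False
    counts, valid = graph.kmer_multiplicities(segment)
    if threshold is None:
        threshold = dynamic_threshold(counts[valid]) if valid.any() else 2
    solid = (counts >= threshold) & valid
    runs = _weak_runs(solid)
    if not runs:
        return segment, False
    modified = False
    out = segment
    # apply right-to-left so earlier coordinates stay valid
    for a, b in reversed(runs):
        left_anchor = segment[a - 1:a - 1 + k]
        right_anchor = segment[b:b + k]
        span = segment[a - 1:b + k]  # anchors inclusive
        max_len = int(len(span) * 1.5) + k
        candidates = _solid_paths(graph, left_anchor, right_anchor,
                                  threshold, max_len, config)
        best = None
        for seq, min_mult in candidates:
            ident = _identity(seq, span)
            if ident < config.min_path_identity:
                continue
            key = (ident, min_mult, [-ord(c) for c in seq])
            if best is None or key > best[0]:
                best = (key, seq)
        if best is not None and best[1] != span:
            out = out[:a - 1] + best[1] + out[b + k:]
            modified = True
    return out, modified


def _solid_fraction(read: str, graph: KmerMultiplicityGraph,
                    config: CorrectionConfig) -> float:
    """Fraction of the read's k-mers that are solid under tile-local thresholds."""
    total = solid = 0
    for start, end in tile_read(len(read), config.tile_length, 0):
        seg = read[start:end]
        if len(seg) < config.k:
            continue
        counts, valid = graph.kmer_multiplicities(seg)
        if not valid.any():
            total += int(valid.size)
            continue
        t = dynamic_threshold(counts[valid])
        total += int(valid.size)
        solid += int(((counts >= t) & valid).sum())
    return solid / total if total else 0.0


def correct_read(read: str, graph: KmerMultiplicityGraph,
                 config: Optional[CorrectionConfig] = None) -> Optional[str]:
    """Correct a read; returns the corrected sequence or DISCARD (None).

    Iteration 1 tiles from offset 0; each further iteration shifts the
    tiling by half a tile, repeating while any tile is modified.  The loop
    ends when one full cycle over both tilings changes nothing (so a second
    call is the identity) or at the ``max_iterations`` safety cap.  Reads
    whose post-correction solid k-mer fraction falls below
    ``min_solid_fraction_keep`` are discarded — this is the
    low-multiplicity read-retention filter.
    """
    config = config or CorrectionConfig()
    if len(read) < config.k:
        return DISCARD
    current = read
    quiet_streak = 0  # consecutive quiescent passes (need one per offset)
    for it in range(config.max_iterations):
        offset = 0 if it % 2 == 0 else config.tile_length // 2
        pieces = []
        any_modified = False
        for start, end in tile_read(len(current), config.tile_length, offset):
            seg, mod = correct_tile(current[start:end], graph, config)
            pieces.append(seg)
            any_modified = any_modified or mod
        current = "".join(pieces)
        quiet_streak = 0 if any_modified else quiet_streak + 1
        if quiet_streak >= 2:  # both tilings quiescent => fixed point
            break
    if _solid_fraction(current, graph, config) < config.min_solid_fraction_keep:
        return DISCARD
    return current
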