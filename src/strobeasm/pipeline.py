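"""End-to-end six-stage assembly driver.

Stage 1 (error correction) and stage 2 (digital normalization) stream
jointly: each corrected read goes straight into the normalizer's
longest-first queue.  The remaining stages — trimming/splitting, unitig
assembly, polishing, transcript extraction — run on the normalized set.
The whole pipeline is a pure function of (reads, options, seed).
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bloom import build_kmer_graph
from .cleanup import trim_split_reads
from .correct import DISCARD, CorrectionConfig, correct_read
from .normalize import (NormalizationConfig, RandstrobeParams,
                        digital_normalize)
from .overlap import find_overlaps
from .polish import polish_unitigs
from .transcripts import Transcript, assemble_transcripts
from .unitig import (assemble_unitigs, build_overlap_graph, detect_polya,
                     prune_by_polya, transitive_reduce)

logger = logging.getLogger("strobeasm")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s %(levelname)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class PipelineOptions:
    k: int = 25
    stranded: bool = True
    tile_length: int = 500
    min_path_identity: float = 0.70
    correction_iterations: int = 10
    min_solid_fraction_keep: float = 0.1
    target_depth: int = 3
    extremity_margin: int = 50
    min_overlap: int = 150
    min_depth: int = 3
    min_segment: int = 200
    max_overhang: int = 25
    polish_max_indel: int = 50
    polish_min_identity: float = 0.70
    binomial_alpha: float = 0.05
    spanning_prob: float = 0.5
    reduction_fuzz: int = 10
    expected_kmers: int = 2_000_000
    seed: int = 0


@dataclass
class PipelineResult:
    transcripts: list[Transcript]
    corrected: list[tuple[str, str]]
    normalized: list[tuple[str, str]]
    segments: list[tuple[str, str]]
    unitigs: list
    polished: list[tuple[str, str]]
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(reads: Sequence[tuple[str, str]],
                 options: Optional[PipelineOptions] = None,
                 short_reads: Optional[Sequence[tuple[str, str]]] = None
                 ) -> PipelineResult:
    """Run stages 1-6 on (id, sequence) reads; returns all intermediates."""
    opt = options or PipelineOptions()
    counts = {"input": len(reads)}
    t0 = time.time()

    # stage 1+2 (streamed): correct each read, hand it to the normalizer
    graph = build_kmer_graph((seq for _, seq in reads),
                             (seq for _, seq in short_reads) if short_reads else None,
                             k=opt.k, canonical=not opt.stranded,
                             expected_kmers=opt.expected_kmers, seed=opt.seed)
    cconf = CorrectionConfig(k=opt.k, tile_length=opt.tile_length,
                             min_path_identity=opt.min_path_identity,
                             max_iterations=opt.correction_iterations,
                             min_solid_fraction_keep=opt.min_solid_fraction_keep)
    corrected = []
    for rid, seq in reads:
        res = correct_read(seq, graph, cconf)
        if res is not DISCARD:
            corrected.append((rid, res))
    counts["corrected"] = len(corrected)
    logger.info("stage 1 error correction: %d/%d reads kept (%.1fs)",
                len(corrected), len(reads), time.time() - t0)

    t0 = time.time()
    params = RandstrobeParams(hash_seed=opt.seed + 17,
                              canonical=not opt.stranded)
    nconf = NormalizationConfig(target_depth=opt.target_depth,
                                extremity_margin=opt.extremity_margin)
    normalized = digital_normalize(corrected, nconf, params)
    counts["normalized"] = len(normalized)
    logger.info("stage 2 normalization: %d reads in MLRS (%.1fs)",
                len(normalized), time.time() - t0)

    t0 = time.time()
    overlaps = find_overlaps(normalized, min_overlap=opt.min_overlap,
                             stranded=opt.stranded)
    segments, _ = trim_split_reads(normalized, overlaps,
                                   min_depth=opt.min_depth,
                                   min_segment=opt.min_segment,
                                   max_overhang=opt.max_overhang)
    counts["segments"] = len(segments)
    logger.info("stage 3 trim/split: %d segments (%.1fs)",
                len(segments), time.time() - t0)

    t0 = time.time()
    seg_overlaps = find_overlaps(segments, min_overlap=opt.min_overlap,
                                 stranded=opt.stranded)
    from .cleanup import contained_ids

    gone = contained_ids(seg_overlaps, opt.max_overhang)
    live = [(sid, s) for sid, s in segments if sid not in gone]
    live_ids = {sid for sid, _ in live}
    live_overlaps = [r for r in seg_overlaps
                     if r.query_id in live_ids and r.target_id in live_ids]
    lengths = {sid: len(s) for sid, s in live}
    signals = {sid: detect_polya(s, read_id=sid) for sid, s in live}
    g = build_overlap_graph(live_overlaps, lengths, stranded=opt.stranded,
                            max_overhang=opt.max_overhang)
    if not opt.stranded:
        g = prune_by_polya(g, signals)
    g = transitive_reduce(g, fuzz=opt.reduction_fuzz)
    unitigs = assemble_unitigs(g, dict(live), signals,
                               stranded=opt.stranded)
    counts["unitigs"] = len(unitigs)
    logger.info("stage 4 unitigs: %d (%.1fs)", len(unitigs), time.time() - t0)

    t0 = time.time()
    polished, read_alignments = polish_unitigs(
        unitigs, corrected, max_indel=opt.polish_max_indel,
        min_identity=opt.polish_min_identity)
    logger.info("stage 5 polish: %d unitigs, %d read alignments (%.1fs)",
                len(polished), len(read_alignments), time.time() - t0)

    t0 = time.time()
    read_signals = {rid: detect_polya(seq, read_id=rid)
                    for rid, seq in corrected} if not opt.stranded else None
    transcripts = assemble_transcripts(polished, read_alignments,
                                       polya_signals=read_signals,
                                       stranded=opt.stranded,
                                       min_overlap=opt.min_overlap,
                                       alpha=opt.binomial_alpha,
                                       spanning_prob=opt.spanning_prob,
                                       fuzz=opt.reduction_fuzz)
    counts["transcripts"] = len(transcripts)
    logger.info("stage 6 transcripts: %d (%.1fs)",
                len(transcripts), time.time() - t0)
    return PipelineResult(transcripts, corrected, normalized, segments,
                          unitigs, polished, counts)
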