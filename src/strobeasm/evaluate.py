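"""Transcript-level assembly evaluation against a reference transcriptome.

Assembled contigs are aligned to the reference transcript set; alignment
segments must pass length (>= 100 nt), identity (>= 95%) and indel
(< 70 nt) gates.  Each contig is then assigned: to a single transcript
(true-positive candidate, preferring truth-set transcripts on ties), as a
misassembly when distinct segments of it match different transcripts
(intragenic vs intergenic by the gene map), as a large-indel contig, or as
unclassified.  Truth transcripts are complete when >= 95% of their length
is covered by assigned contigs, partial when covered at all, otherwise
missing.  Recall, FDR, F1 and redundancy follow the standard
assembly-benchmarking formulas:

    FD  = FP + MA + LI + UC          FDR = FD / (FD + TP)
    F1  = TP / [TP + 0.5 (FD + FN)]  redundancy = (contigs for TP) / TP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .overlap import MapAlignment, map_queries


@dataclass
class EvalConfig:
    min_segment: int = 100
    min_identity: float = 0.95
    max_indel: int = 70
    complete_fraction: float = 0.95


@dataclass
class EvalReport:
    complete: int = 0
    partial: int = 0
    missing: int = 0
    TP: int = 0
    FP: int = 0
    MA_intra: int = 0
    MA_inter: int = 0
    LI: int = 0
    UC: int = 0
    tp_contigs: int = 0
    recall: float = 0.0
    FDR: float = 0.0
    F1: float = 0.0
    redundancy: float = float("nan")

    @property
    def FD(self) -> int:
        return self.FP + self.MA_intra + self.MA_inter + self.LI + self.UC

    def as_dict(self) -> dict:
        return {
            "complete": self.complete, "partial": self.partial,
            "missing": self.missing, "TP": self.TP, "FP": self.FP,
            "MA_intra": self.MA_intra, "MA_inter": self.MA_inter,
            "LI": self.LI, "UC": self.UC, "FD": self.FD,
            "tp_contigs": self.tp_contigs, "recall": self.recall,
            "FDR": self.FDR, "F1": self.F1, "redundancy": self.redundancy,
        }


def _segments_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True when intervals share more than half of the shorter one."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    shorter = min(a[1] - a[0], b[1] - b[0])
    return shorter > 0 and (hi - lo) * 2 > shorter


def filter_and_assign(contig_alignments: Sequence[MapAlignment],
                      truth_ids: set[str],
                      gene_map: Mapping[str, str],
                      contig_ids: Sequence[str],
                      config: Optional[EvalConfig] = None) -> dict[str, dict]:
    """Per-contig category and transcript assignment.

    Returns contig_id → {"category": TP|MA_intra|MA_inter|LI|UC|FP,
    "transcript": id or None, "intervals": [(start, end) on transcript]}.
    """
    config = config or EvalConfig()
    for t in truth_ids:
        if t not in gene_map:
            raise ValueError(f"truth id {t} absent from reference annotation")
    by_contig: dict[str, list[MapAlignment]] = {cid: [] for cid in contig_ids}
    for a in contig_alignments:
        if a.query_id in by_contig:
            by_contig[a.query_id].append(a)
    out = {}
    for cid, alns in by_contig.items():
        pre_gate = [a for a in alns
                    if (a.query_end - a.query_start) >= config.min_segment
                    and a.identity >= config.min_identity]
        surviving = [a for a in pre_gate if a.largest_indel < config.max_indel]
        if not surviving:
            if pre_gate:  # killed only by the indel gate
                out[cid] = {"category": "LI", "transcript": None, "intervals": []}
            else:
                out[cid] = {"category": "UC", "transcript": None, "intervals": []}
            continue
        # best surviving alignment per transcript
        best_per_t: dict[str, MapAlignment] = {}
        for a in surviving:
            cur = best_per_t.get(a.target_id)
            if cur is None or (a.identity * (a.query_end - a.query_start)) > \
                    (cur.identity * (cur.query_end - cur.query_start)):
                best_per_t[a.target_id] = a
        # misassembly: alignments to different transcripts on distinct
        # contig segments (overlapping-segment multi-hits are just
        # ambiguous placements, resolved below)
        t_list = sorted(best_per_t)
        split_pairs = []
        for i in range(len(t_list)):
            for j in range(i + 1, len(t_list)):
                a = best_per_t[t_list[i]]
                b = best_per_t[t_list[j]]
                if not _segments_overlap((a.query_start, a.query_end),
                                         (b.query_start, b.query_end)):
                    split_pairs.append((t_list[i], t_list[j]))
        if split_pairs:
            kinds = set()
            for ta, tb in split_pairs:
                same_gene = gene_map.get(ta) == gene_map.get(tb) and \
                    gene_map.get(ta) is not None
                kinds.add("MA_intra" if same_gene else "MA_inter")
            cat = "MA_inter" if "MA_inter" in kinds else "MA_intra"
            out[cid] = {"category": cat, "transcript": None, "intervals": []}
            continue
        # single placement: pick best, ties resolve toward the truth set
        def rank(t):
            a = best_per_t[t]
            score = a.identity * (a.query_end - a.query_start)
            return (round(score, 6), t in truth_ids, t)

        chosen = max(t_list, key=rank)
        a = best_per_t[chosen]
        cat = "TP" if chosen in truth_ids else "FP"
        out[cid] = {"category": cat, "transcript": chosen,
                    "intervals": [(x.target_start, x.target_end)
                                  for x in surviving if x.target_id == chosen]}
    return out


def reconstruction_levels(assignments: Mapping[str, dict],
                          truth_ids: set[str],
                          transcript_lengths: Mapping[str, int],
                          config: Optional[EvalConfig] = None) -> dict[str, str]:
    """Per-truth-transcript level: complete / partial / missing."""
    config = config or EvalConfig()
    covered: dict[str, list[tuple[int, int]]] = {t: [] for t in truth_ids}
    for info in assignments.values():
        t = info.get("transcript")
        if t in covered:
            covered[t].extend(info["intervals"])
    levels = {}
    for t in sorted(truth_ids):
        ivs = sorted(covered[t])
        total = 0
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        frac = total / transcript_lengths[t]
        if frac >= config.complete_fraction:
            levels[t] = "complete"
        elif frac > 0:
            levels[t] = "partial"
        else:
            levels[t] = "missing"
    return levels


def compute_metrics(complete: int, partial: int, missing: int,
                    FP: int = 0, MA_intra: int = 0, MA_inter: int = 0,
                    LI: int = 0, UC: int = 0, tp_contigs: int = 0) -> EvalReport:
    """Recall/FDR/F1/redundancy from category counts."""
    rep = EvalReport(complete=complete, partial=partial, missing=missing,
                     FP=FP, MA_intra=MA_intra, MA_inter=MA_inter, LI=LI,
                     UC=UC, tp_contigs=tp_contigs)
    rep.TP = complete + partial
    FD, TP, FN = rep.FD, rep.TP, missing
    truth_total = TP + FN
    rep.recall = 100.0 * TP / truth_total if truth_total else 0.0
    if FD + TP:
        rep.FDR = FD / (FD + TP)
    else:
        rep.FDR = 0.0
    denom = TP + 0.5 * (FD + FN)
    rep.F1 = TP / denom if denom else 0.0
    rep.redundancy = tp_contigs / TP if TP else float("nan")
    return rep


def evaluate_assembly(contigs: Sequence[tuple[str, str]],
                      reference: Sequence[tuple[str, str]],
                      truth_ids: set[str],
                      gene_map: Mapping[str, str],
                      config: Optional[EvalConfig] = None,
                      alignments: Optional[Sequence[MapAlignment]] = None
                      ) -> EvalReport:
    """Align contigs to the reference and produce the full report.

    ``alignments`` may be supplied (e.g. parsed from an external aligner's
    PAF after base-level refinement); otherwise the internal mapper runs.
    """
    config = config or EvalConfig()
    if alignments is None:
        alignments = map_queries(list(contigs), list(reference),
                                 min_span=config.min_segment)
    contig_ids = [cid for cid, _ in contigs]
    assignments = filter_and_assign(alignments, truth_ids, gene_map,
                                    contig_ids, config)
    lengths = {rid: len(s) for rid, s in reference}
    levels = reconstruction_levels(assignments, truth_ids, lengths, config)
    cats = [info["category"] for info in assignments.values()]
    tp_contigs = sum(1 for info in assignments.values()
                     if info["category"] == "TP"
                     and levels.get(info["transcript"]) in ("complete", "partial"))
    # FP counts contigs assigned to non-truth reference transcripts
    return compute_metrics(
        complete=sum(1 for v in levels.values() if v == "complete"),
        partial=sum(1 for v in levels.values() if v == "partial"),
        missing=sum(1 for v in levels.values() if v == "missing"),
        FP=cats.count("FP"),
        MA_intra=cats.count("MA_intra"),
        MA_inter=cats.count("MA_inter"),
        LI=cats.count("LI"),
        UC=cats.count("UC"),
        tp_contigs=tp_contigs,
    )
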