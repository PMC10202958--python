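"""Stage 5 — alignment-based polishing of unitigs with corrected reads.

Stage-1 output reads are aligned back to the unitigs; alignments with a
large indel (default > 50 nt) or low identity (default < 70%) are dropped
so that short alternatively spliced exons are not voted away by reads of a
sibling isoform.  The surviving alignments feed a per-column pileup
consensus: the weighted majority base wins each column, deletions are
explicit votes, insertions are accepted when more than half the covering
reads support them, and ties keep the draft base (minimal change).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bloom import revcomp
from .overlap import MapAlignment, map_queries

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def filter_polish_alignments(alignments: Iterable[MapAlignment],
                             max_indel: int = 50,
                             min_identity: float = 0.70) -> list[MapAlignment]:
    """Keep alignments with largest indel <= max_indel and identity >= min."""
    return [a for a in alignments
            if a.largest_indel <= max_indel and a.identity >= min_identity]


def polish_sequence(unitig_seq: str,
                    alignments: Sequence[MapAlignment],
                    read_sequences: Mapping[str, str]) -> str:
    """Pileup-consensus polish of one unitig from filtered read alignments."""
    n = len(unitig_seq)
    votes: list[Counter] = [Counter() for _ in range(n)]
    coverage = [0] * n
    # insertions keyed by the column they precede
    ins_votes: dict[int, Counter] = defaultdict(Counter)
    ins_cov = [0] * (n + 1)
    for aln in alignments:
        qseq = read_sequences[aln.query_id]
        qseg = qseq[aln.query_start:aln.query_end]
        if aln.strand == "-":
            qseg = revcomp(qseg)
        qi, ti = 0, aln.target_start
        for num, op in _CIG_RE.findall(aln.cigar):
            num = int(num)
            if op in "=XM":
                for _ in range(num):
                    votes[ti][qseg[qi]] += 1
                    coverage[ti] += 1
                    qi += 1
                    ti += 1
            elif op == "D":  # read lacks these unitig bases
                for _ in range(num):
                    votes[ti]["-"] += 1
                    coverage[ti] += 1
                    ti += 1
            elif op == "I":  # read carries extra bases before column ti
                ins_votes[ti][qseg[qi:qi + num]] += 1
                qi += num
        # count insertion coverage: every read whose alignment spans a
        # junction could have voted an insertion there
        for j in range(aln.target_start + 1, ti):
            ins_cov[j] += 1
    out = []
    for i in range(n):
        if ins_votes.get(i) and ins_cov[i] > 0:
            seqv, cnt = ins_votes[i].most_common(1)[0]
            if cnt * 2 > ins_cov[i]:
                out.append(seqv)
        if coverage[i] == 0:
            out.append(unitig_seq[i])
            continue
        draft = unitig_seq[i]
        counts = votes[i]
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        # tie rule: any tied column keeps the draft base (minimal change)
        choice = draft if (draft in winners or len(winners) > 1) else winners[0]
        if choice != "-":
            out.append(choice)
    return "".join(out)


def polish_unitigs(unitigs: Sequence, reads: Sequence[tuple[str, str]],
                   max_indel: int = 50, min_identity: float = 0.70,
                   map_kwargs: dict | None = None
                   ) -> tuple[list[tuple[str, str]], list[MapAlignment]]:
    """Map reads to unitigs, filter, and polish each unitig.

    Returns (polished (id, seq) list, the filtered alignments) — the
    alignments are reused by the transcript-assembly stage for unitig read
    counts.
    """
    targets = [(u.id, u.seq) for u in unitigs]
    alignments = map_queries(reads, targets, **(map_kwargs or {}))
    kept = filter_polish_alignments(alignments, max_indel, min_identity)
    by_unitig: dict[str, list[MapAlignment]] = defaultdict(list)
    for a in kept:
        by_unitig[a.target_id].append(a)
    read_seqs = dict(reads)
    polished = []
    for uid, useq in targets:
        polished.append((uid, polish_sequence(useq, by_unitig.get(uid, []),
                                              read_seqs)))
    return polished, kept
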