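# Methods

`strobeasm` is a reference-free assembler for noisy long cDNA/dRNA reads.
It reconstructs transcript sequences directly from reads — no genome, no
annotation — through six stages: (1) alignment-free error correction on a
Bloom-filter de Bruijn graph, (2) digital normalization with randstrobes,
(3) depth-based trimming and chimera splitting, (4) overlap-graph unitig
assembly with poly(A)-guided strand resolution, (5) pileup-consensus
polishing, and (6) greedy, expression-guided transcript extraction.  This
note records the model behind each stage, the parameters that matter, the
numerical choices made where the design was open, and what the synthetic
benchmarks do and do not demonstrate.

## Probabilistic k-mer structures

k-mer membership lives in a plain Bloom filter and k-mer/strobemer
multiplicities in a counting Bloom filter, giving the de Bruijn graph a
memory footprint independent of the number of distinct k-mers stored
exactly.  Both structures have strictly one-sided error: membership has no
false negatives, and reported counts never fall below true counts
(conservative update inflates them only on hash collisions).  Sizing
follows the standard analytic formulas from a user-supplied expected item
count and a 1% target false-positive rate; hashing is double hashing on a
splitmix64 mix, fully determined by a seed.  Counter cells saturate at
2^8 − 1 rather than wrapping.  k = 25 by default (odd, so canonical k-mers
are well defined); canonical (strand-collapsed) k-mers are used for
unstranded cDNA input and as-read k-mers for stranded dRNA input.

## Stage 1 — error correction

Each read is split into 500 nt tiles evaluated independently, so the
weak/solid multiplicity threshold adapts to transcript-level expression
differences along the read.  Within a tile the threshold is
t = max(2, ceil(q25/10)), refined to the deepest valley of the tile's
multiplicity histogram below its median when one exists.  *This rule is a
reconstruction*: it separates an error mode (multiplicity ≈ 1) from the
tile-local coverage mode, which is the documented intent, but the original
procedure is not published in detail.  Runs of weak k-mers flanked by two
solid anchors are replaced by a solid path found by bounded best-first
search in the de Bruijn graph (priority: maximize the path's minimum
multiplicity; ≤ 64 expanded states; path length ≤ 1.5 × span + k), and the
replacement is accepted only if its global-alignment identity against the
original span is ≥ 70%.  Ties between candidate paths break by higher
minimum multiplicity, then lexicographically.

Correction repeats while any tile was modified, alternating the tiling
offset by half a tile so errors at tile boundaries get anchored in the
next pass; the loop ends when a full cycle over both tilings changes
nothing — which makes correction idempotent — with a safety cap of 10
passes.  A read whose solid-k-mer fraction after correction is below 0.1
is discarded (the low-multiplicity read-retention filter); reads shorter
than k are discarded with a reason.

## Stage 2 — digital normalization

The goal is a minimal longest reads set (MLRS) supporting a target depth
of 3×.  Depth is approximated by multiplicities of randstrobes of order 3:
a fixed 10 nt first strobe anchored at each position, and two further
strobes each chosen within a [15, 50) nt window downstream of the previous
strobe's end, minimizing (chain_hash + candidate_hash) mod q.  Linked
seeds tolerate the mismatches and indels that survive stage 1, which
contiguous k-mers would not.  The strobe length and windows are this
package's choice (the construction spans ≈ 110 nt per strobemer); they are
configurable.  For unstranded input each strobe's 10-mer is hashed
canonically so both strands of a transcript feed the same counts.

Reads are visited longest-first (ties keep input order).  A read is
*represented* when strobemers with multiplicity ≥ 3 cover its interior —
everything more than 50 nt from either end — without a gap ("covered"
meaning anchor-to-last-strobe-end intervals).  Represented reads are
dropped; every other read joins the MLRS and increments its strobemer
counts that are still below the target depth.  Reads too short to yield a
strobemer are kept: dropping them would conflate normalization with
filtering.  Because counts are one-sided overestimates, normalization can
only be more aggressive than exact counting, never less.

## Overlap detection

All-vs-all overlaps use canonical minimizers (k = 15, window 10), per-pair
colinear chaining (banded DP, max gap 100 nt), and greedy exact extension
of chain ends; identity is estimated from seed coverage.  Overhang
classification (threshold 25 nt) labels records dovetail, containment, or
internal.  Mutually contained (near-identical) reads keep the longer
member (ties: smaller id) — dropping both would erase the locus.  Overlaps
can be imported/exported as 12-column PAF, so an external all-vs-all
aligner can be substituted verbatim.  Structural indel sizes are measured
from diagonal jumps between consecutive chain seeds as well as from the
base-level alignment: unit-cost alignment can scatter one long gap into
several small ones, and the chain recovers the true gap size.

## Stage 3 — trimming and splitting

A read position is sufficiently covered when its depth — 1 for the read
itself plus the number of overlap intervals covering it — reaches 3,
i.e. the region overlaps at least two other reads.  Maximal runs of
sufficient depth at least 200 nt long are emitted (the 200 nt floor is this
package's choice; shorter fragments are unassemblable noise).
Under-covered heads and tails are thereby trimmed, and internal
under-covered valleys split the read: a fusion junction of a chimeric read
is spanned by no genuine overlap, so alignments end raggedly on both sides
of it and leave a depth gap.  Contained reads are not emitted but their
overlaps still count as coverage evidence.  A caveat follows from the
mechanism: if alignments abut a junction *exactly* (error-free fused
sequences), no depth gap forms and the junction can escape detection;
with realistic noise the ragged alignment ends expose it.

## Stage 4 — unitig assembly

Vertices are (segment, orientation) pairs — forward-only for stranded
input, strand-symmetric for cDNA — and edges are dovetail overlaps.
Poly(A) tails (≥ 10 A at ≥ 0.9 purity within the terminal 20 nt, extended
leftward through the run; parameters are this package's choice) and
poly(T) heads fix read orientations: a poly(A)-tailed vertex loses
outgoing edges (nothing extends a 3' end), a poly(T)-headed one loses
incoming edges.  Applied over both orientations this disconnects the
head-to-head joins that arise between convergent antisense genes in
unstranded data.  Transitive edges are removed when a two-step path
explains them within a 10 nt fuzz (residual indels); the check runs
against the original edge set so removal order cannot matter.  Unitigs are
maximal unambiguous paths, spliced first-read-verbatim plus each
successor's novel suffix; in unstranded mode each unitig and its mirror
collapse to one record (canonical orientation: poly(A) at the 3' end when
known, else lexicographic minimum).

## Stage 5 — polishing

Corrected reads are mapped back to unitigs.  Alignments with an indel
larger than 50 nt or identity below 70% are removed so that reads of an
exon-skipping sibling isoform cannot vote a spliced exon out of the
unitig; survivors feed a per-column pileup consensus with explicit
deletion votes, insertions accepted above 50% of covering reads, and ties
keeping the draft base (minimal change, deterministic).  Known limitation:
the indel gate guarantees protection only for exons larger than the gate —
a 40 nt exon's deletion passes the 50 nt filter and its survival then
rests on the consensus majority and the tie rule (covered by tests for
both regimes).

## Stage 6 — transcript extraction

Polished unitigs are overlapped and annotated with length-normalized read
counts (aligned bases / unitig length, so a read straddling two unitigs
contributes fractionally to each) and per-edge spanning-read support,
counted as reads with filtered alignments to both incident unitigs.  An
edge is removed when an exact one-sided binomial test finds its support
significantly below expectation: with n = round(min(count_u, count_v)) and
p = 0.5, remove if P(X ≤ s) < 0.05; edges with n < 3 are kept for lack of
evidence.  The (n, p, one-sidedness) formulation is a reconstruction and
all three knobs are exposed.  In unstranded mode unitigs are reoriented by
the majority strand of their poly(A)-read alignments and edges consistent
only with anti-preferred orientations are dropped.  Transcripts are then
extracted greedily: vertices sorted once by descending count (ties: longer
unitig, then id) seed bidirectional extensions that always take the
highest-count neighbour and stop at a dead-end, an in-path revisit
(cycle), or a zero-count vertex; after each path is emitted its vertices
are flagged from seeding and decremented by the path minimum, so a shared
exon's unitig can serve several isoforms while expression bookkeeping
stays conserved.  Termination is guaranteed because every seed is flagged
when visited.

## Evaluation

Contigs are aligned to the reference transcript set; segments must be
≥ 100 nt, ≥ 95% identity, with indels < 70 nt.  A contig whose surviving
alignments hit more than one transcript on *distinct* contig segments is a
misassembly (intragenic/intergenic by the gene map); a contig whose same
segment hits several transcripts is merely ambiguous and resolves to the
best hit, ties preferring the truth set.  A contig whose alignments fail
only the indel gate is a large-indel contig (LI); one with no alignments
at all is unclassified (UC); LI/UC/MA contigs are exclusive of TP.  Truth
transcripts are complete at ≥ 95% covered length (union of assigned
segments), partial above zero, else missing.  Metrics: recall = percentage
of truth transcripts reconstructed; FD = FP + MA + LI + UC;
FDR = FD/(FD + TP); F1 = TP/[TP + 0.5(FD + FN)]; redundancy =
TP-representing contigs / TP.

## Synthetic data

The simulator emulates what the assembler assumes about real data:
multi-isoform genes assembled from exon pools with a shared 5' exon
(creating the fork/bubble graph topologies stages 4 and 6 must resolve),
log-uniform expression over a configurable fold range, iid per-base
substitution/insertion/deletion errors, 3'-anchored truncation (the 3'
end survives; cDNA length bias), poly(A) tails, random strand in cDNA
mode, and optional chimeric reads fusing two fragments.  One seeded RNG
stream makes outputs byte-identical across runs.  It does *not* model
homopolymer-length errors, position- or sequence-dependent error profiles,
quality scores, intron retention, or adapter artifacts — so passing tests
demonstrate the algorithmic contracts under the stated statistical
assumptions, not performance on any particular sequencing chemistry.

A dedicated fixture builds two convergent genes overlapping antisense at
their 3' ends — the configuration in which an unstranded assembler would
chimerically join two genes unless poly(A) evidence resolves strand.

## Problem sizes and defaults

The test suite and the reproduction script run deliberately small
configurations chosen to exercise every code path at desk scale: 10–50
transcripts, 120–1,500 reads, 20× coverage for correction benchmarks,
600 reads for the end-to-end assembly.  Defaults throughout — k = 25,
tile 500 nt, identity gate 0.70, target depth 3, margin 50 nt, min overlap
150 nt, min depth 3, polish gates 50 nt / 0.70, evaluation gates
100 nt / 0.95 / 70 nt — are the workflow's standard operating point;
parameters invented here (strobe geometry, poly(A) detection, 200 nt
minimum segment, binomial test shape) are documented above as this
package's choices and are configurable.
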