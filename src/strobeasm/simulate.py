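"""Synthetic transcriptomes and noisy long reads with ground truth.

The generator emulates the statistical structure the assembler is built
for: multi-isoform genes sharing exons (fork/bubble topologies in the
overlap graph), log-scale expression variation, per-base
substitution/insertion/deletion errors, 3'-biased length truncation,
poly(A) tails, unknown strand in cDNA mode, and a configurable fraction of
chimeric (fused) reads.  Everything is driven by one seeded RNG stream, so
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .bloom import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    n_genes: int = 2
    isoforms_per_gene: tuple[int, int] = (2, 2)
    exons_per_gene: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (150, 400)
    expression_fold_range: tuple[float, float] = (1.0, 200.0)
    substitution_rate: float = 0.02
    insertion_rate: float = 0.005
    deletion_rate: float = 0.005
    truncation_fraction: tuple[float, float] = (0.6, 1.0)
    full_length_prob: float = 0.5
    polya_length: tuple[int, int] = (12, 30)
    stranded: bool = True
    chimera_rate: float = 0.0
    seed: int = 1

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate,
                  self.deletion_rate, self.chimera_rate):
            if not (0 <= r < 1):
                raise ValueError("rates must be in [0, 1)")


@dataclass
class Transcriptome:
    sequences: list  # (transcript_id, seq)
    gene_map: dict   # transcript_id -> gene_id
    exon_structure: dict  # transcript_id -> tuple of exon indices
    expression: dict  # transcript_id -> relative expression


@dataclass
class ReadTruth:
    read_id: str
    transcript_id: str
    strand: str
    is_chimera: bool
    n_errors: int


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_transcriptome(config: SimConfig) -> Transcriptome:
    """Genes built from exon pools; isoforms of a gene share >= 1 exon.

    Every isoform includes its gene's first exon (a shared 5' exon, which
    creates the Y-fork topologies the assembler must resolve) and a
    distinct subset of the remaining exons in positional order.
    """
    rng = np.random.default_rng(config.seed)
    lo_i, hi_i = config.isoforms_per_gene
    lo_e, hi_e = config.exons_per_gene
    if lo_e < 2:
        raise ValueError("genes need >= 2 exons to make distinct isoforms")
    sequences, gene_map, structure, expression = [], {}, {}, {}
    for gi in range(config.n_genes):
        gene_id = f"gene{gi}"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exons = [_random_seq(rng, int(rng.integers(config.exon_length[0],
                                                   config.exon_length[1] + 1)))
                 for _ in range(n_exons)]
        n_iso = int(rng.integers(lo_i, hi_i + 1))
        chosen: set[tuple[int, ...]] = set()
        attempts = 0
        while len(chosen) < n_iso:
            attempts += 1
            if attempts > 1000:
                raise ValueError("infeasible isoform configuration")
            incl = [0] + [e for e in range(1, n_exons)
                          if rng.random() < 0.7]
            key = tuple(incl)
            if key in chosen:
                continue
            chosen.add(key)
        for ti, key in enumerate(sorted(chosen)):
            tid = f"{gene_id}_t{ti}"
            seq = "".join(exons[e] for e in key)
            sequences.append((tid, seq))
            gene_map[tid] = gene_id
            structure[tid] = key
            lo_f, hi_f = config.expression_fold_range
            expression[tid] = float(np.exp(rng.uniform(np.log(lo_f),
                                                       np.log(hi_f))))
    return Transcriptome(sequences, gene_map, structure, expression)


def apply_errors(seq: str, rng: np.random.Generator, sub: float, ins: float,
                 dele: float) -> tuple[str, int]:
    """iid per-base substitution/insertion/deletion; returns (seq, n_errors)."""
    if sub + ins + dele == 0:
        return seq, 0
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    u = rng.random(codes.size)
    out = []
    n_err = 0
    for i, b in enumerate(codes):
        r = u[i]
        if r < dele:
            n_err += 1
            continue
        if r < dele + ins:
            out.append(chr(b))
            out.append("ACGT"[rng.integers(0, 4)])
            n_err += 1
            continue
        if r < dele + ins + sub:
            cur = chr(b)
            alt = "ACGT"[rng.integers(0, 4)]
            while alt == cur:
                alt = "ACGT"[rng.integers(0, 4)]
            out.append(alt)
            n_err += 1
        else:
            out.append(chr(b))
    return "".join(out), n_err


def simulate_reads(transcriptome: Transcriptome, config: SimConfig,
                   n_reads: int) -> tuple[list, list]:
    """Noisy long reads plus a ground-truth table.

    Returns ([(read_id, seq)], [ReadTruth]).  Per-transcript read counts
    are proportional to expression; each read keeps the transcript 3' end
    (3'-anchored truncation), gains a poly(A) tail, and in cDNA
    (unstranded) mode is emitted on a random strand.
    """
    rng = np.random.default_rng(config.seed + 1)
    tids = [tid for tid, _ in transcriptome.sequences]
    seqs = dict(transcriptome.sequences)
    expr = np.array([transcriptome.expression[t] for t in tids])
    if expr.sum() <= 0:
        raise ValueError("zero expression everywhere")
    probs = expr / expr.sum()
    assignment = rng.choice(len(tids), size=n_reads, p=probs)
    reads, truth = [], []

    def one_fragment(tid: str) -> str:
        t = seqs[tid]
        if rng.random() < config.full_length_prob:
            frac = 1.0
        else:
            frac = rng.uniform(*config.truncation_fraction)
        keep = max(1, int(round(len(t) * frac)))
        frag = t[len(t) - keep:]  # 3'-anchored
        tail = "A" * int(rng.integers(config.polya_length[0],
                                      config.polya_length[1] + 1))
        return frag + tail

    for i in range(n_reads):
        tid = tids[assignment[i]]
        rid = f"read{i}"
        is_chimera = rng.random() < config.chimera_rate
        if is_chimera:
            other = tids[int(rng.integers(0, len(tids)))]
            frag_a = one_fragment(tid)
            frag_b = one_fragment(other)
            # fuse two half-fragments
            base = frag_a[: max(1, len(frag_a) // 2)] + \
                frag_b[max(1, len(frag_b) // 2):]
        else:
            base = one_fragment(tid)
        noisy, n_err = apply_errors(base, rng, config.substitution_rate,
                                    config.insertion_rate,
                                    config.deletion_rate)
        strand = "+"
        if not config.stranded and rng.random() < 0.5:
            noisy = revcomp(noisy)
            strand = "-"
        reads.append((rid, noisy))
        truth.append(ReadTruth(rid, tid, strand, is_chimera, n_err))
    return reads, truth


def make_antisense_pair(seed: int = 1, unique_len: int = 900,
                        shared_len: int = 500) -> Transcriptome:
    """Two convergent genes overlapping antisense at their 3' ends.

    Transcript A = uniqueA + core; transcript B = uniqueB + revcomp(core).
    A forward read of A dovetails the reverse complement of a read of B, so
    an unstranded assembler would chimerically join the genes unless
    poly(A)-tail evidence fixes each read's orientation — the configuration
    strand resolution must refuse to join.
    """
    rng = np.random.default_rng(seed)
    core = _random_seq(rng, shared_len)
    ua = _random_seq(rng, unique_len)
    ub = _random_seq(rng, unique_len)
    ta = ua + core
    tb = ub + revcomp(core)
    seqs = [("geneA_t0", ta), ("geneB_t0", tb)]
    return Transcriptome(
        sequences=seqs,
        gene_map={"geneA_t0": "geneA", "geneB_t0": "geneB"},
        exon_structure={"geneA_t0": (0, 1), "geneB_t0": (0, 1)},
        expression={"geneA_t0": 10.0, "geneB_t0": 10.0},
    )


def write_reference_fasta(transcriptome: Transcriptome, path) -> None:
    from .fastx import write_fasta

    write_fasta(transcriptome.sequences, path)


def write_truth_tsv(truth: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\tstrand\tis_chimera\tn_errors\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.transcript_id}\t{t.strand}\t"
                     f"{int(t.is_chimera)}\t{t.n_errors}\n")


def write_annotation_tsv(transcriptome: Transcriptome, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\texons\n")
        for tid, _ in transcriptome.sequences:
            exons = ",".join(map(str, transcriptome.exon_structure[tid]))
            fh.write(f"{tid}\t{transcriptome.gene_map[tid]}\t{exons}\n")
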