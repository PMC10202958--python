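"""Probabilistic set/counter structures and the Bloom-filter de Bruijn graph.

The assembler stores k-mer membership in a plain Bloom filter and approximate
k-mer (and strobemer) multiplicities in a counting Bloom filter.  Both are
one-sided: a Bloom filter never reports an inserted key as absent, and the
counting filter never reports a count below the true count.  The de Bruijn
graph is implicit — neighbours of a k-mer are found by querying the four
possible single-base extensions against the membership filter.

k-mers are held as 2-bit-packed integers (A=0, C=1, G=2, T=3), which keeps
every hot path vectorisable with numpy.  k must be ≤ 31 so a k-mer fits in a
uint64 with headroom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)

# -- base encoding -----------------------------------------------------------

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (preserves N)."""
    return seq.translate(COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes; non-ACGT positions become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def kmer_array(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of ``seq`` as packed uint64, plus a validity mask.

    Position i holds the k-mer starting at i; positions whose window touches
    a non-ACGT base are flagged invalid (their packed value is unspecified).
    """
    codes = encode_bases(seq)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(windows == 255).any(axis=1)
    shifts = np.arange(k - 1, -1, -1, dtype=np.uint64) * np.uint64(2)
    packed = ((windows.astype(np.uint64) & np.uint64(3)) << shifts).sum(
        axis=1, dtype=np.uint64
    )
    return packed, valid


def canonical_kmer_array(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Strand-collapsed k-mers: elementwise min of forward and revcomp."""
    fwd, valid = kmer_array(seq, k)
    if fwd.size == 0:
        return fwd, valid
    rc_all, _ = kmer_array(revcomp(seq), k)
    rc_aligned = rc_all[::-1]
    return np.minimum(fwd, rc_aligned), valid


def kmer_to_str(kmer: int, k: int) -> str:
    codes = [(int(kmer) >> (2 * (k - 1 - i))) & 3 for i in range(k)]
    return "".join("ACGT"[c] for c in codes)


def kmer_from_str(kmer: str) -> int:
    packed, valid = kmer_array(kmer, len(kmer))
    if packed.size != 1 or not valid[0]:
        raise ValueError(f"not a valid ACGT k-mer: {kmer!r}")
    return int(packed[0])


# -- hashing -----------------------------------------------------------------


def splitmix64(x: np.ndarray | int) -> np.ndarray | np.uint64:
    """Deterministic 64-bit finalising mixer (vectorised over uint64 arrays)."""
    with np.errstate(over="ignore"):
        z = (np.uint64(x) + np.uint64(0x9E3779B97F4A7C15)) & _MASK64
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9) & _MASK64
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB) & _MASK64
        return z ^ (z >> np.uint64(31))


_M64 = (1 << 64) - 1


def _mix_int(x: int) -> int:
    """Python-int splitmix64, bit-identical to :func:`splitmix64`."""
    z = (x + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def _hash_bytes(key: bytes, seed: int) -> int:
    # FNV-1a over the bytes, then a splitmix finalise with the seed folded in.
    h = 0xCBF29CE484222325
    for b in key:
        h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return int(splitmix64(np.uint64(h ^ (seed & 0xFFFFFFFFFFFFFFFF))))


def _as_u64(keys) -> np.ndarray:
    arr = np.asarray(keys, dtype=np.uint64)
    return np.atleast_1d(arr)


class _ProbeMixin:
    """Double hashing: h_i = h1 + i*h2 mod size, from one 64-bit hash."""

    num_hashes: int
    _size: int
    _seed: int

    def _key_to_u64(self, key) -> np.uint64:
        if isinstance(key, (bytes, bytearray)):
            if len(key) == 0:
                raise ValueError("empty key")
            return np.uint64(_hash_bytes(bytes(key), self._seed))
        if isinstance(key, str):
            return self._key_to_u64(key.encode("ascii"))
        return splitmix64(np.uint64(int(key)) ^ np.uint64(self._seed & 0xFFFFFFFFFFFFFFFF))

    def _probes(self, keys_u64: np.ndarray) -> np.ndarray:
        """(n, num_hashes) array of slot indices."""
        with np.errstate(over="ignore"):
            mixed = splitmix64(keys_u64 ^ np.uint64(self._seed & 0xFFFFFFFFFFFFFFFF))
            h2 = splitmix64(mixed) | np.uint64(1)
            i = np.arange(self.num_hashes, dtype=np.uint64)
            probes = (mixed[:, None] + i[None, :] * h2[:, None]) & _MASK64
        return (probes % np.uint64(self._size)).astype(np.int64)

    def _probes_scalar(self, key_int: int) -> list[int]:
        """Pure-python probe list, bit-identical to :meth:`_probes`."""
        mixed = _mix_int(key_int ^ (self._seed & _M64))
        h2 = _mix_int(mixed) | 1
        size = self._size
        return [((mixed + i * h2) & _M64) % size for i in range(self.num_hashes)]


def bloom_parameters(expected_items: int, fpr: float) -> tuple[int, int]:
    """Analytic (bit-capacity, hash-count) for a target false-positive rate."""
    if expected_items <= 0 or not (0 < fpr < 1):
        raise ValueError("expected_items must be > 0 and 0 < fpr < 1")
    m = math.ceil(-expected_items * math.log(fpr) / (math.log(2) ** 2))
    h = max(1, round(m / expected_items * math.log(2)))
    return m, h


class BloomFilter(_ProbeMixin):
    """Plain bit-array Bloom filter with no false negatives."""

    def __init__(self, bit_capacity: int, num_hashes: int, seed: int = 0):
        if bit_capacity <= 0 or num_hashes <= 0:
            raise ValueError("bit_capacity and num_hashes must be positive")
        self.bit_capacity = int(bit_capacity)
        self.num_hashes = int(num_hashes)
        self.inserted_count = 0
        self._seed = int(seed)
        self._size = self.bit_capacity
        self._bits = np.zeros((self.bit_capacity + 7) // 8, dtype=np.uint8)

    @classmethod
    def from_expected(cls, expected_items: int, fpr: float = 0.01, seed: int = 0):
        m, h = bloom_parameters(expected_items, fpr)
        return cls(m, h, seed=seed)

    def expected_fpr(self) -> float:
        """Analytic false-positive rate at the current load."""
        h, m, n = self.num_hashes, self.bit_capacity, self.inserted_count
        return (1.0 - math.exp(-h * n / m)) ** h

    def _set(self, probes: np.ndarray) -> None:
        flat = probes.ravel()
        np.bitwise_or.at(self._bits, flat >> 3, np.uint8(1) << (flat & 7).astype(np.uint8))

    def _test(self, probes: np.ndarray) -> np.ndarray:
        bits = (self._bits[probes >> 3] >> (probes & 7).astype(np.uint8)) & 1
        return bits.all(axis=1)

    def insert(self, key) -> None:
        self._set(self._probes(_as_u64(self._key_to_u64(key))))
        self.inserted_count += 1

    def contains(self, key) -> bool:
        return bool(self._test(self._probes(_as_u64(self._key_to_u64(key))))[0])

    def contains_scalar(self, key_int: int) -> bool:
        """Fast membership test for a packed key (hot path of graph walks)."""
        bits = self._bits
        for p in self._probes_scalar(key_int):
            if not (bits[p >> 3] >> (p & 7)) & 1:
                return False
        return True

    def insert_array(self, keys_u64: np.ndarray) -> None:
        keys_u64 = _as_u64(keys_u64)
        if keys_u64.size == 0:
            return
        self._set(self._probes(keys_u64))
        self.inserted_count += int(keys_u64.size)

    def contains_array(self, keys_u64: np.ndarray) -> np.ndarray:
        keys_u64 = _as_u64(keys_u64)
        if keys_u64.size == 0:
            return np.empty(0, dtype=bool)
        return self._test(self._probes(keys_u64))


class CountingBloomFilter(_ProbeMixin):
    """Counting Bloom filter: one-sided (over-counting) multiset.

    Cells are uint32 internally; reported counts saturate at
    ``2**counter_bits - 1``.  Increments use conservative update (only the
    currently-minimal cells advance), which keeps reported ≥ true while
    reducing collision inflation.
    """

    def __init__(self, counter_capacity: int, counter_bits: int = 8,
                 num_hashes: int = 4, seed: int = 0):
        if counter_capacity <= 0 or num_hashes <= 0 or counter_bits <= 0:
            raise ValueError("capacity, hashes and counter_bits must be positive")
        self.counter_capacity = int(counter_capacity)
        self.counter_bits = int(counter_bits)
        self.num_hashes = int(num_hashes)
        self._seed = int(seed)
        self._size = self.counter_capacity
        self._max = (1 << self.counter_bits) - 1
        self._cells = np.zeros(self.counter_capacity, dtype=np.uint32)

    @classmethod
    def from_expected(cls, expected_items: int, fpr: float = 0.01,
                      counter_bits: int = 8, seed: int = 0):
        m, h = bloom_parameters(expected_items, fpr)
        # counter cells replace bits one-for-one; same collision analysis.
        return cls(m, counter_bits=counter_bits, num_hashes=h, seed=seed)

    @property
    def saturation_max(self) -> int:
        return self._max

    def increment(self, key, by: int = 1) -> int:
        """Add ``by`` to a key's count; returns the new reported count."""
        if by < 0:
            raise ValueError("increments must be non-negative")
        probes = self._probes(_as_u64(self._key_to_u64(key)))[0]
        if by:
            cells = self._cells[probes]
            target = min(int(cells.min()) + by, 1 << 31)
            self._cells[probes] = np.maximum(cells, target)
        return self.count(key)

    def count(self, key) -> int:
        probes = self._probes(_as_u64(self._key_to_u64(key)))[0]
        return min(int(self._cells[probes].min()), self._max)

    def count_scalar(self, key_int: int) -> int:
        """Fast reported count for a packed key."""
        cells = self._cells
        lo = None
        for p in self._probes_scalar(key_int):
            c = cells[p]
            if lo is None or c < lo:
                lo = c
        return min(int(lo), self._max)

    def increment_array(self, keys_u64: np.ndarray, by: int = 1) -> None:
        """Increment each key once per occurrence (conservative update)."""
        keys_u64 = _as_u64(keys_u64)
        if keys_u64.size == 0 or by == 0:
            return
        # group duplicates so repeated keys in one batch count correctly
        uniq, counts = np.unique(keys_u64, return_counts=True)
        probes = self._probes(uniq)
        cells = self._cells[probes]
        target = np.minimum(cells.min(axis=1) + counts.astype(np.uint32) * np.uint32(by),
                            np.uint32(1 << 31))
        np.maximum.at(self._cells, probes.ravel(),
                      np.repeat(target, self.num_hashes))

    def count_array(self, keys_u64: np.ndarray) -> np.ndarray:
        keys_u64 = _as_u64(keys_u64)
        if keys_u64.size == 0:
            return np.empty(0, dtype=np.int64)
        probes = self._probes(keys_u64)
        return np.minimum(self._cells[probes].min(axis=1), self._max).astype(np.int64)


# -- k-mer de Bruijn graph ---------------------------------------------------


@dataclass
class KmerMultiplicityGraph:
    """Bloom-filter de Bruijn graph: k-mer membership plus multiplicities.

    ``canonical=True`` collapses strands (cDNA / unstranded input);
    ``canonical=False`` stores k-mers as read (stranded dRNA input).
    """

    k: int = 25
    canonical: bool = True
    expected_kmers: int = 1_000_000
    fpr: float = 0.01
    seed: int = 0
    membership: BloomFilter = field(init=False)
    multiplicity: CountingBloomFilter = field(init=False)

    def __post_init__(self):
        if self.k < 5 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 5")
        if self.k > 31:
            raise ValueError("k must fit a 64-bit packed word (k <= 31)")
        self.membership = BloomFilter.from_expected(self.expected_kmers, self.fpr,
                                                    seed=self.seed)
        self.multiplicity = CountingBloomFilter.from_expected(self.expected_kmers,
                                                              self.fpr,
                                                              seed=self.seed + 1)
        self._short_warned = False

    # packing helpers respect the strand mode
    def _pack(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        if self.canonical:
            return canonical_kmer_array(seq, self.k)
        return kmer_array(seq, self.k)

    def ingest_read(self, seq: str, copies: int = 1) -> int:
        """Insert every valid k-mer of a read; returns number ingested."""
        packed, valid = self._pack(seq)
        keys = packed[valid]
        if keys.size == 0:
            if not self._short_warned and len(seq) < self.k:
                import warnings

                warnings.warn("read shorter than k contributes no k-mers")
                self._short_warned = True
            return 0
        self.membership.insert_array(keys)
        if copies == 1:
            self.multiplicity.increment_array(keys)
        else:
            for _ in range(copies):
                self.multiplicity.increment_array(keys)
        return int(keys.size)

    def build(self, long_reads: Iterable[str],
              short_reads: Optional[Iterable[str]] = None) -> "KmerMultiplicityGraph":
        """Ingest long reads (and optional short reads) into the graph."""
        n = 0
        for seq in long_reads:
            n += 1
            self.ingest_read(seq)
        if n == 0:
            raise ValueError("empty input read stream")
        if short_reads is not None:
            for seq in short_reads:
                self.ingest_read(seq)
        return self

    def contains_kmer(self, kmer: str) -> bool:
        packed, valid = self._pack(kmer)
        return bool(valid[0]) and bool(self.membership.contains_array(packed)[0])

    def kmer_multiplicities(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-position multiplicities of a sequence's k-mers.

        Returns (counts, valid); counts are 0 where the k-mer is not a graph
        member or the window is invalid.
        """
        packed, valid = self._pack(seq)
        counts = np.zeros(packed.size, dtype=np.int64)
        if packed.size:
            member = np.zeros(packed.size, dtype=bool)
            member[valid] = self.membership.contains_array(packed[valid])
            counts[member] = self.multiplicity.count_array(packed[member])
        return counts, valid

    def pack_state(self, kmer: str) -> tuple[int, int]:
        """(forward, revcomp) packed ints of a k-mer, for fast graph walks."""
        packed, valid = kmer_array(kmer, self.k)
        if packed.size != 1 or not valid[0]:
            raise ValueError(f"not a valid k-mer of length {self.k}: {kmer!r}")
        rc_packed, _ = kmer_array(revcomp(kmer), self.k)
        return int(packed[0]), int(rc_packed[0])

    def successor_states(self, fwd: int, rc: int) -> list[tuple[int, int, int, int]]:
        """Right extensions present in the graph, as packed-int states.

        Returns (base_code, new_fwd, new_rc, multiplicity) tuples; the
        incremental revcomp update keeps canonicalization O(1) per step.
        """
        k = self.k
        mask = (1 << (2 * k)) - 1
        shift = 2 * (k - 1)
        member = self.membership.contains_scalar
        count = self.multiplicity.count_scalar
        out = []
        for b in range(4):
            nf = ((fwd << 2) & mask) | b
            nr = (rc >> 2) | ((3 - b) << shift)
            key = min(nf, nr) if self.canonical else nf
            if member(key):
                out.append((b, nf, nr, count(key)))
        return out

    def neighbors(self, kmer: str, direction: str = "right") -> list[tuple[str, int]]:
        """Extensions of a k-mer present in the graph, with multiplicities."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        if direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")
        out = []
        for base in "ACGT":
            cand = kmer[1:] + base if direction == "right" else base + kmer[:-1]
            packed, valid = self._pack(cand)
            if not valid[0]:
                continue
            if self.membership.contains_array(packed)[0]:
                out.append((cand, int(self.multiplicity.count_array(packed)[0])))
        return out


def build_kmer_graph(long_reads: Iterable[str],
                     short_reads: Optional[Iterable[str]] = None,
                     k: int = 25, canonical: bool = True,
                     expected_kmers: int = 1_000_000, fpr: float = 0.01,
                     seed: int = 0) -> KmerMultiplicityGraph:
    """Build the k-mer multiplicity graph from read streams."""
    graph = KmerMultiplicityGraph(k=k, canonical=canonical,
                                  expected_kmers=expected_kmers, fpr=fpr, seed=seed)
    return graph.build(long_reads, short_reads)
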