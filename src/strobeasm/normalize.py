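"""Stage 2 — digital normalization with randstrobes (MLRS selection).

Read depth is reduced to a small target (default 3×) by selecting the
minimal longest reads set (MLRS): reads are visited longest-first, and a
read is kept only if some region of it (more than ``extremity_margin`` nt
from either end) is not yet covered by strobemers whose multiplicity in the
kept set has reached the target depth.  Strobemer multiplicities live in a
counting Bloom filter, so depth estimates are one-sided overestimates.

Randstrobes (order 3 by default) are linked seeds: a fixed first strobe and
two further strobes each chosen pseudo-randomly within a downstream window,
which makes the construct tolerant of mismatches and small indels between
reads of the same transcript — exactly the comparison a noisy-long-read
normalizer needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bloom import CountingBloomFilter, kmer_array, revcomp, splitmix64

REPRESENTED = "REPRESENTED"
NOT_REPRESENTED = "NOT_REPRESENTED"

_Q = np.uint64((1 << 20) - 3)  # modulus for the strobe link function


@dataclass
class RandstrobeParams:
    order: int = 3
    strobe_length: int = 10
    window_min: int = 15
    window_max: int = 50
    hash_seed: int = 17
    canonical: bool = False  # per-strobe strand collapsing for cDNA input

    def __post_init__(self):
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if not (self.window_min < self.window_max):
            raise ValueError("window_min must be < window_max")
        if self.strobe_length > self.window_min:
            raise ValueError("strobe_length must be <= window_min")

    @property
    def max_span(self) -> int:
        """Largest possible anchor-to-end extent of one strobemer."""
        return self.strobe_length + (self.order - 1) * (self.window_max - 1 + self.strobe_length)


@dataclass
class NormalizationConfig:
    target_depth: int = 3
    extremity_margin: int = 50

    def __post_init__(self):
        if self.target_depth < 1 or self.extremity_margin < 0:
            raise ValueError("target_depth >= 1 and margin >= 0 required")


def _strobe_hashes(seq: str, params: RandstrobeParams) -> np.ndarray:
    """Per-position hash of each strobe-length substring (0 where invalid)."""
    ell = params.strobe_length
    fwd, valid = kmer_array(seq, ell)
    if fwd.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    if params.canonical:
        rc_all, _ = kmer_array(revcomp(seq), ell)
        fwd = np.minimum(fwd, rc_all[::-1])
    h = splitmix64(fwd ^ np.uint64(params.hash_seed))
    h = np.where(valid, h, np.uint64(0))
    # mark invalid with 0 so downstream selection avoids them via the mask
    return h, valid


def randstrobes(seq: str, params: RandstrobeParams) -> list[tuple[int, int, int]]:
    """Randstrobes of a sequence: (anchor_start, covered_end, hash64).

    One strobemer per anchor position where the full selection window fits.
    Strobe j+1 starts in [prev_end + window_min, prev_end + window_max),
    chosen to minimise (chain_hash + strobe_hash) mod q; the final hash
    chains all selected strobes, so it is order-dependent and deterministic
    for a given seed.
    """
    ell = params.strobe_length
    n = len(seq)
    if n < ell + (params.order - 1) * params.window_max:
        return []
    hashes, valid = _strobe_hashes(seq, params)
    npos = hashes.size  # number of strobe start positions
    # an anchor is valid when the nominal full construct fits the sequence
    n_anchor = n - (ell + (params.order - 1) * params.window_max) + 1
    if n_anchor <= 0:
        return []
    anchors = np.arange(n_anchor)
    chain = hashes[:n_anchor].copy()
    ok = valid[:n_anchor].copy()
    pos_end = anchors + ell  # end position of last selected strobe
    offsets = np.arange(params.window_min, params.window_max)
    for _ in range(params.order - 1):
        cand_idx = pos_end[:, None] + offsets[None, :]
        in_range = cand_idx < npos  # clip windows at the sequence end
        cand_idx_safe = np.where(in_range, cand_idx, 0)
        cand_h = hashes[cand_idx_safe]
        cand_ok = valid[cand_idx_safe] & in_range
        with np.errstate(over="ignore"):
            score = (chain[:, None] + cand_h) % _Q
        score = np.where(cand_ok, score, np.uint64(1 << 62))
        pick = score.argmin(axis=1)
        rows = np.arange(cand_idx.shape[0])
        sel_idx = cand_idx_safe[rows, pick]
        ok &= cand_ok[rows, pick]
        with np.errstate(over="ignore"):
            chain = splitmix64(chain * np.uint64(0x9E3779B97F4A7C15) ^ hashes[sel_idx])
        pos_end = sel_idx + ell
    out = []
    for i in range(n_anchor):
        if ok[i]:
            out.append((int(anchors[i]), int(pos_end[i]), int(chain[i])))
    return out


class StrobemerCounter:
    """Counting Bloom filter over strobemer hashes of the current MLRS."""

    def __init__(self, params: RandstrobeParams | None = None,
                 expected_items: int = 2_000_000, fpr: float = 0.01,
                 counter_bits: int = 8, seed: int = 0):
        self.params = params or RandstrobeParams()
        self.cbf = CountingBloomFilter.from_expected(expected_items, fpr,
                                                     counter_bits=counter_bits,
                                                     seed=seed)

    def counts(self, hashes: np.ndarray) -> np.ndarray:
        return self.cbf.count_array(hashes)

    def increment_below(self, hashes: np.ndarray, target_depth: int) -> None:
        """Increment only strobemers whose count is still below target depth."""
        if hashes.size == 0:
            return
        below = self.cbf.count_array(hashes) < target_depth
        self.cbf.increment_array(np.unique(hashes[below]))


def classify_read_representation(read: str, counter: StrobemerCounter,
                                 config: NormalizationConfig,
                                 params: RandstrobeParams | None = None) -> str:
    """REPRESENTED iff deep strobemers cover the read interior gap-free.

    The interior is [margin, len - margin); a strobemer covers
    [anchor, covered_end).  Reads too short to yield strobemers are
    conservatively NOT_REPRESENTED (kept).
    """
    params = params or counter.params
    strobes = randstrobes(read, params)
    if not strobes:
        return NOT_REPRESENTED
    lo, hi = config.extremity_margin, len(read) - config.extremity_margin
    if hi <= lo:
        # no interior to cover: represented iff any strobemer is deep
        hashes = np.array([h for _, _, h in strobes], dtype=np.uint64)
        deep = counter.counts(hashes) >= config.target_depth
        return REPRESENTED if deep.any() else NOT_REPRESENTED
    hashes = np.array([h for _, _, h in strobes], dtype=np.uint64)
    deep = counter.counts(hashes) >= config.target_depth
    cover = lo
    for (a, e, _), d in zip(strobes, deep):
        if not d:
            continue
        if a > cover:
            return NOT_REPRESENTED  # uncovered gap before this strobemer
        cover = max(cover, e)
        if cover >= hi:
            return REPRESENTED
    return REPRESENTED if cover >= hi else NOT_REPRESENTED


def digital_normalize(reads: Sequence[tuple[str, str]],
                      config: NormalizationConfig | None = None,
                      params: RandstrobeParams | None = None,
                      counter: StrobemerCounter | None = None,
                      return_log: bool = False):
    """Select the minimal longest reads set from (id, sequence) pairs.

    Reads are evaluated longest-first (ties keep input order); each
    not-yet-represented read joins the MLRS and its sub-target-depth
    strobemer counts are incremented by one.  Represented reads are dropped
    and do not increment.  Returns retained reads in original input order
    (sequences verbatim); with ``return_log`` also a decision list.
    """
    config = config or NormalizationConfig()
    params = params or RandstrobeParams()
    counter = counter or StrobemerCounter(params)
    order = sorted(range(len(reads)), key=lambda i: -len(reads[i][1]))
    keep = set()
    log = []
    for i in order:
        rid, seq = reads[i]
        decision = classify_read_representation(seq, counter, config, params)
        if decision == NOT_REPRESENTED:
            keep.add(i)
            strobes = randstrobes(seq, params)
            if strobes:
                hashes = np.array([h for _, _, h in strobes], dtype=np.uint64)
                counter.increment_below(hashes, config.target_depth)
        log.append((rid, decision))
    retained = [reads[i] for i in range(len(reads)) if i in keep]
    if return_log:
        return retained, log
    return retained
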