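"""Low-level nucleotide encoding and k-mer hashing helpers.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3; anything else maps to
255 and is treated as never-matching.  k-mers are packed 2 bits per base
into uint64, which caps k at 31.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_LUT[_b] = _i
    ENCODE_LUT[_b + 32] = _i  # lowercase

DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes (all < 4) back into an A/C/G/T string."""
    return DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of encoded bases; valid only for codes < 4."""
    return (3 - codes)[::-1]


def revcomp_str(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq.upper()))


def rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer hash at every start position of a 1-D code vector.

    Returns ``(hashes, valid)`` where ``valid[i]`` is False when the window
    starting at ``i`` contains a non-ACGT code.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        h = (h << two) | codes[j : j + n].astype(np.uint64)
    bad = np.concatenate(([0], np.cumsum(codes > 3)))
    valid = (bad[k:] - bad[:-k]) == 0
    return h, valid


def encode_batch(seqs, length: int) -> np.ndarray:
    """Encode equal-length strings into an (n, length) code matrix."""
    joined = "".join(seqs)
    flat = ENCODE_LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return flat.reshape(len(seqs), length)


def decode_batch(codes: np.ndarray) -> list:
    """Decode an (n, L) code matrix into n strings (one big conversion)."""
    n, L = codes.shape
    joined = DECODE_LUT[codes.reshape(-1)].tobytes().decode("ascii")
    return [joined[i * L : (i + 1) * L] for i in range(n)]


class KmerLookup:
    """Bucketed lookup of query k-mers in a sorted k-mer/position index.

    A prefix-bucket table bounds each query to a handful of candidate slots,
    which is much faster than a full binary search per query.
    """

    def __init__(self, kmers_sorted: np.ndarray, positions: np.ndarray, k: int,
                 bucket_bits: int = 22):
        self.kmers = kmers_sorted
        self.positions = positions
        bits = 2 * k
        bucket_bits = min(bucket_bits, bits)
        self.shift = np.uint64(bits - bucket_bits)
        n_buckets = 1 << bucket_bits
        buckets = (kmers_sorted >> self.shift).astype(np.int64)
        counts = np.bincount(buckets, minlength=n_buckets)
        self.starts = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)

    def lookup(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query_index, ref_position) hits for a uint64 query array."""
        b = (queries >> self.shift).astype(np.int64)
        lo = self.starts[b]
        hi = self.starts[b + 1]
        width = hi - lo
        out_q: list = []
        out_p: list = []
        qi = np.flatnonzero(width > 0)
        cur = lo[qi].copy()
        end = hi[qi]
        while qi.size:
            hit = self.kmers[cur] == queries[qi]
            if hit.any():
                out_q.append(qi[hit])
                out_p.append(self.positions[cur[hit]])
            cur += 1
            alive = cur < end
            if not alive.all():
                qi, cur, end = qi[alive], cur[alive], end[alive]
        if not out_q:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return np.concatenate(out_q), np.concatenate(out_p)


def matrix_kmers(codes: np.ndarray, k: int, offsets) -> np.ndarray:
    """k-mer hashes of a (n_reads, L) code matrix at the given column offsets.

    Returns an (n_reads, len(offsets)) uint64 array.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.shape[0]
    out = np.empty((n, len(offsets)), dtype=np.uint64)
    two = np.uint64(2)
    for oi, off in enumerate(offsets):
        sub = codes[:, off : off + k].astype(np.uint64)
        h = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            h = (h << two) | sub[:, j]
        out[:, oi] = h
    return out
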