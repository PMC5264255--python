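"""Exact k-mer anchoring utilities.

Contigs from the same sample (and the simulator's error-free contigs) are
near-identical to their sources, so exact shared-k-mer chaining stands in
for a full aligner: a query position is anchored when its k-mer occurs in
the reference, and maximal co-linear runs of anchors form match blocks.
K-mers are handled as rolling 2-bit integer codes (k <= 31), vectorized
with numpy.
"""

from __future__ import annotations

import numpy as np

from .formats import revcomp

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i

_INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)


def _base_codes(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int, canonical: bool = True) -> np.ndarray:
    """2-bit packed k-mer codes per position (invalid windows = sentinel).

    With ``canonical`` the code is the minimum of the forward and
    reverse-complement encodings, making the value strand-independent.
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 62-bit packing")
    codes = _base_codes(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    two = np.uint64(2)
    for i in range(k):
        window = codes[i : i + n]
        bad |= window >= 4
        fwd = (fwd << two) | window.astype(np.uint64)
    if canonical:
        rc = np.zeros(n, dtype=np.uint64)
        comp = (3 - codes.astype(np.int16)).astype(np.uint64)  # valid bases only
        for i in range(k - 1, -1, -1):
            rc = (rc << two) | comp[i : i + n]
        out = np.minimum(fwd, rc)
    else:
        out = fwd
    out[bad] = _INVALID
    return out


class KmerIndex:
    """Sorted canonical k-mer code set over reference sequences."""

    def __init__(self, sequences, k: int = 31, positions: bool = False):
        self.k = k
        seqs = list(sequences.values()) if isinstance(sequences, dict) else list(sequences)
        chunks = [kmer_codes(s, k) for s in seqs if len(s) >= k]
        if chunks:
            allc = np.concatenate(chunks)
            self.codes = np.unique(allc[allc != _INVALID])
        else:
            self.codes = np.empty(0, dtype=np.uint64)

    def hits(self, query: str) -> np.ndarray:
        """Boolean per-position mask: query k-mer present in the index."""
        q = kmer_codes(query, self.k)
        if q.size == 0 or self.codes.size == 0:
            return np.zeros(q.size, dtype=bool)
        idx = np.searchsorted(self.codes, q)
        idx[idx >= self.codes.size] = self.codes.size - 1
        return (self.codes[idx] == q) & (q != _INVALID)

    def __contains__(self, kmer: str) -> bool:
        return bool(self.hits(kmer).any()) if len(kmer) == self.k else False


def _covered_bases(hit_positions: np.ndarray, k: int) -> int:
    """Union size of intervals [p, p + k) over sorted hit positions."""
    if hit_positions.size == 0:
        return 0
    gaps = np.diff(hit_positions)
    return int(k + np.minimum(gaps, k).sum())


def covered_fraction(query: str, index: KmerIndex) -> float:
    """Fraction of query bases covered by k-mers present in the index."""
    n = len(query)
    if n < index.k:
        return 0.0
    hits = index.hits(query)
    return _covered_bases(np.flatnonzero(hits), index.k) / n


def reference_coverage(queries, reference: str, k: int = 31) -> float:
    """Fraction of reference positions covered by exact k-mers from queries."""
    n = len(reference)
    if n < k:
        return 0.0
    index = KmerIndex(list(queries), k=k)
    hits = index.hits(reference)
    return _covered_bases(np.flatnonzero(hits), k) / n


def match_blocks(query: str, reference: str, k: int = 31) -> list[int]:
    """Lengths of maximal co-linear exact-match blocks of query on reference.

    Blocks are runs of query k-mers hitting consecutive reference positions
    on a common diagonal (either strand); each run of length r covers
    r + k - 1 bases.
    """
    ref = kmer_codes(reference, k, canonical=False)
    order = np.argsort(ref, kind="stable")
    sorted_ref = ref[order]
    blocks = []
    for q in (query, revcomp(query)):
        qc = kmer_codes(q, k, canonical=False)
        if qc.size == 0:
            continue
        lo = np.searchsorted(sorted_ref, qc, side="left")
        hi = np.searchsorted(sorted_ref, qc, side="right")
        has = (hi > lo) & (qc != _INVALID)
        active: dict[int, int] = {}  # diagonal -> expected ref pos
        lengths: dict[int, int] = {}
        for i in np.flatnonzero(has).tolist():
            for p in order[lo[i] : hi[i]].tolist():
                diag = p - i
                if active.get(diag) == p:
                    lengths[diag] += 1
                else:
                    if diag in lengths:
                        blocks.append(lengths[diag] + k - 1)
                    lengths[diag] = 1
                active[diag] = p + 1
        blocks.extend(l + k - 1 for l in lengths.values())
    return sorted(blocks, reverse=True)
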