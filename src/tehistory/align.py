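"""Local alignment engine: affine-gap Smith-Waterman plus a k-mer prefilter.

The pipeline's searches are dominated by reads that contain no element copy at
all, so every search first routes reads through :func:`kmer_candidates`, which
keeps only reads sharing at least ``min_shared`` exact k-mers with a target
library (checked on both strands).  Surviving reads are aligned with a
numba-compiled Smith-Waterman with affine gaps.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``
(the first gapped position pays the opening penalty only).  Scores are
configurable; defaults are match +2, mismatch -3, gap open -5, gap extend -2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import encode, revcomp

DEFAULT_SCORES = (2, -3, -5, -2)  # match, mismatch, gap_open, gap_extend


@dataclass
class LocalAlignment:
    """One local alignment of a query against a target.

    Intervals are 1-based closed, in the respective original sequences.
    ``pairs`` lists aligned index pairs (q, t), 0-based, -1 for a gap on that
    side; it covers the local alignment span only.
    """

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    pairs: np.ndarray  # (n, 2) int32

    @property
    def n_columns(self) -> int:
        return self.pairs.shape[0]


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**8, dtype=np.int32)  # gap in query (move along target)
    F = np.full((n + 1, m + 1), -10**8, dtype=np.int32)  # gap in target (move along query)
    # traceback: 0 stop, 1 diag, 2 from E (left), 3 from F (up)
    TB = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            E[i, j] = e_open if e_open >= e_ext else e_ext
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            F[i, j] = f_open if f_open >= f_ext else f_ext
            # N (code 5) never matches
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            tb = 0
            if diag > h:
                h = diag
                tb = 1
            if E[i, j] > h:
                h = E[i, j]
                tb = 2
            if F[i, j] > h:
                h = F[i, j]
                tb = 3
            H[i, j] = h
            TB[i, j] = tb
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, TB, best, bi, bj


@njit(cache=True)
def _sw_traceback(TB, E, F, H, bi, bj, gap_open, gap_extend):
    # walk back from (bi, bj) to the first cell with tb == 0
    maxlen = bi + bj
    pairs = np.empty((maxlen, 2), dtype=np.int32)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0 and TB[i, j] != 0:
        tb = TB[i, j]
        if tb == 1:
            pairs[k, 0] = i - 1
            pairs[k, 1] = j - 1
            k += 1
            i -= 1
            j -= 1
        elif tb == 2:
            # gap in query: consume target columns while inside the E run
            while j > 0:
                pairs[k, 0] = -1
                pairs[k, 1] = j - 1
                k += 1
                opened = H[i, j - 1] + gap_open == E[i, j]
                j -= 1
                if opened:
                    break
        else:
            while i > 0:
                pairs[k, 0] = i - 1
                pairs[k, 1] = -1
                k += 1
                opened = H[i - 1, j] + gap_open == F[i, j]
                i -= 1
                if opened:
                    break
    return pairs[:k][::-1].copy()


def smith_waterman(
    query: str | np.ndarray,
    target: str | np.ndarray,
    match: int = DEFAULT_SCORES[0],
    mismatch: int = DEFAULT_SCORES[1],
    gap_open: int = DEFAULT_SCORES[2],
    gap_extend: int = DEFAULT_SCORES[3],
) -> LocalAlignment | None:
    """Best local alignment of ``query`` vs ``target``; None if score 0."""
    q = encode(query) if isinstance(query, str) else query
    t = encode(target) if isinstance(target, str) else target
    if len(q) == 0 or len(t) == 0:
        return None
    H, E, F, TB, best, bi, bj = _sw_fill(
        q, t, np.int32(match), np.int32(mismatch), np.int32(gap_open), np.int32(gap_extend)
    )
    if best <= 0:
        return None
    pairs = _sw_traceback(TB, E, F, H, bi, bj, np.int32(gap_open), np.int32(gap_extend))
    qcols = pairs[:, 0][pairs[:, 0] >= 0]
    tcols = pairs[:, 1][pairs[:, 1] >= 0]
    return LocalAlignment(
        score=int(best),
        query_start=int(qcols.min()) + 1,
        query_end=int(qcols.max()) + 1,
        target_start=int(tcols.min()) + 1,
        target_end=int(tcols.max()) + 1,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# k-mer prefilter


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """All k-mer integer codes of an encoded sequence; k-mers touching an N
    or any non-ACGT code are dropped."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    valid = arr < 4
    vals = arr.astype(np.int64).copy()
    vals[~valid] = 0
    codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
    ok = np.ones(len(arr) - k + 1, dtype=bool)
    for off in range(k):
        codes = codes * 4 + vals[off : off + len(codes)]
        ok &= valid[off : off + len(codes)]
    return codes[ok]


class KmerIndex:
    """Sorted array of the distinct k-mers of a sequence library."""

    def __init__(self, sequences: list[str], k: int = 12):
        self.k = k
        parts = [_kmer_codes(encode(s), k) for s in sequences if len(s) >= k]
        allk = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        self.kmers = np.unique(allk)

    def shared_count(self, seq_codes: np.ndarray) -> int:
        codes = _kmer_codes(seq_codes, self.k)
        if len(codes) == 0 or len(self.kmers) == 0:
            return 0
        pos = np.searchsorted(self.kmers, codes)
        pos[pos == len(self.kmers)] = len(self.kmers) - 1
        return int(np.count_nonzero(self.kmers[pos] == codes))


def kmer_candidates(
    reads: list[tuple[str, str]], index: KmerIndex, min_shared: int = 3
) -> list[tuple[int, str]]:
    """Reads sharing >= min_shared k-mers with the library, with orientation.

    Returns (read index, strand) where strand is '+' or '-'; a read may appear
    on both strands if both pass (palindromic or chimeric cases).
    """
    out: list[tuple[int, str]] = []
    for i, (_, s) in enumerate(reads):
        fwd = index.shared_count(encode(s))
        rev = index.shared_count(encode(revcomp(s)))
        # keep a strand when it passes the floor and is not dwarfed by the other
        if fwd >= min_shared and 2 * fwd >= rev:
            out.append((i, "+"))
        if rev >= min_shared and 2 * rev >= fwd:
            out.append((i, "-"))
    return out
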