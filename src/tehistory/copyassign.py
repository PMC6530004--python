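"""Library search, coverage filtering, copy assignment and CpG-masked divergence.

This module plays the role a RepeatMasker search plays in classic repeat
annotation pipelines: reads are searched (both strands) against a library of
consensus sequences with a local affine-gap aligner, hits covering less than a
minimum fraction of the consensus are discarded, and every retained copy is
assigned to the subfamily whose consensus it diverges least from.  Percent
divergence is computed with the consensus's CpG columns excluded from both
numerator and denominator, because methylation-driven CpG hypermutation would
otherwise inflate the apparent age of CpG-rich elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORES, KmerIndex, smith_waterman
from .seqio import CpGMask, ReadSet, cpg_mask, encode, revcomp

GAP_CODE = 4


@dataclass
class ConsensusSequence:
    """An element/subfamily consensus, optionally anchored in a shared column
    frame (``frame_start`` = 1-based frame column of its first base)."""

    consensus_id: str
    sequence: str
    mask: CpGMask | None = None
    frame_start: int = 1

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"{self.consensus_id}: consensus must be ACGT only")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_cpg_mask(self) -> "ConsensusSequence":
        return ConsensusSequence(
            self.consensus_id, self.sequence, cpg_mask(self.sequence, self.consensus_id), self.frame_start
        )


@dataclass
class Hit:
    """One read-vs-consensus local alignment observation."""

    read_id: str
    species: str
    consensus_id: str
    read_start: int
    read_end: int
    consensus_start: int
    consensus_end: int
    strand: str
    pairs: np.ndarray  # (n, 2) int32: (consensus index, read index), 0-based, -1 = gap
    read_codes: np.ndarray  # oriented read (uint8)
    query_coverage: float
    identity: float
    divergence_cpg_masked: float = math.nan

    def consensus_row(self, length: int) -> np.ndarray:
        """Project the read onto consensus columns (insertions dropped)."""
        row = np.full(length, GAP_CODE, dtype=np.uint8)
        ci = self.pairs[:, 0]
        ri = self.pairs[:, 1]
        keep = ci >= 0
        ci = ci[keep]
        ri = ri[keep]
        has_base = ri >= 0
        row[ci[has_base]] = self.read_codes[ri[has_base]]
        return row


def _extend_to_overlap(aln, q_len: int, t_len: int):
    """Extend a local alignment along its end diagonals to the full
    query/target overlap.

    Local alignment maximizes score and therefore trims mismatch-dense ends;
    for divergence estimation those trimmed columns are homologous and must
    count, otherwise old copies look systematically younger.  Gap-free
    diagonal extension restores them.
    """
    qs, ts = aln.pairs[0]
    ext = min(qs, ts)
    left = np.stack([np.arange(qs - ext, qs), np.arange(ts - ext, ts)], axis=1).astype(np.int32)
    qe, te = aln.pairs[-1]
    ext_r = min(q_len - 1 - qe, t_len - 1 - te)
    right = np.stack(
        [np.arange(qe + 1, qe + 1 + ext_r), np.arange(te + 1, te + 1 + ext_r)], axis=1
    ).astype(np.int32)
    pairs = np.concatenate([left, aln.pairs, right])
    return type(aln)(
        score=aln.score,
        query_start=int(qs - ext) + 1,
        query_end=int(qe + ext_r) + 1,
        target_start=int(ts - ext) + 1,
        target_end=int(te + ext_r) + 1,
        pairs=pairs,
    )


def _hit_from_alignment(aln, read_id, species, consensus, strand, read_codes) -> Hit:
    aln = _extend_to_overlap(aln, len(consensus.sequence), len(read_codes))
    cov = 100.0 * (aln.query_end - aln.query_start + 1) / len(consensus.sequence)
    q = encode(consensus.sequence)
    qi, ti = aln.pairs[:, 0], aln.pairs[:, 1]
    both = (qi >= 0) & (ti >= 0)
    matches = int(((q[qi[both]] == read_codes[ti[both]]) & (q[qi[both]] < 4)).sum())
    ident = 100.0 * matches / aln.n_columns
    return Hit(
        read_id=read_id,
        species=species,
        consensus_id=consensus.consensus_id,
        read_start=aln.target_start,
        read_end=aln.target_end,
        consensus_start=aln.query_start,
        consensus_end=aln.query_end,
        strand=strand,
        pairs=aln.pairs,
        read_codes=read_codes,
        query_coverage=cov,
        identity=ident,
    )


def search(
    reads: ReadSet,
    consensi: list[ConsensusSequence],
    min_identity: float = 60.0,
    min_coverage: float = 90.0,
    scores: tuple[int, int, int, int] = DEFAULT_SCORES,
    prefilter_k: int = 12,
    prefilter_min_shared: int = 3,
    max_hits_per_read: int = 2,
) -> list[Hit]:
    """Search all reads against a consensus library; keep covering hits.

    Both strands are searched; each read is aligned against the library
    consensus it shares the most k-mers with (candidate consensi are ranked by
    exact k-mer sharing, which tracks alignment identity).  Hits below
    ``min_coverage`` percent of the consensus length or ``min_identity``
    percent identity are discarded.  A read spanning two element copies can
    yield up to ``max_hits_per_read`` non-overlapping hits.
    """
    if not consensi:
        raise ValueError("empty consensus library")
    per_cons = [KmerIndex([c.sequence], k=prefilter_k) for c in consensi]
    combined = KmerIndex([c.sequence for c in consensi], k=prefilter_k)
    floor = prefilter_min_shared
    hits: list[Hit] = []
    for read_id, seq in reads:
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        # cheap gate against the whole library before per-consensus routing
        if max(combined.shared_count(fwd), combined.shared_count(rev)) < floor:
            continue
        shared = [
            (idx.shared_count(fwd), idx.shared_count(rev), j) for j, idx in enumerate(per_cons)
        ]
        cands = []
        for f, r, j in shared:
            if f >= floor and 2 * f >= r:
                cands.append((f, "+", j))
            if r >= floor and 2 * r >= f:
                cands.append((r, "-", j))
        if not cands:
            continue
        cands.sort(key=lambda t: (-t[0], t[1], t[2]))
        found: list[Hit] = []
        for _, strand, j in cands[:3]:
            cons = consensi[j]
            codes = fwd if strand == "+" else rev
            segments = [(0, len(codes))]
            for h in found:  # only search outside already-claimed read span
                s0, e0 = h.read_start - 1, h.read_end
                segments = [
                    seg
                    for old in segments
                    for seg in ((old[0], min(old[1], s0)), (max(old[0], e0), old[1]))
                    if seg[1] - seg[0] >= min_coverage / 100.0 * len(cons.sequence)
                ]
            for s0, e0 in segments:
                aln = smith_waterman(encode(cons.sequence), codes[s0:e0], *scores)
                if aln is None:
                    continue
                aln.pairs[:, 1][aln.pairs[:, 1] >= 0] += s0
                aln = type(aln)(
                    aln.score,
                    aln.query_start,
                    aln.query_end,
                    aln.target_start + s0,
                    aln.target_end + s0,
                    aln.pairs,
                )
                h = _hit_from_alignment(aln, read_id, reads.species, cons, strand, codes)
                if h.query_coverage > min_coverage and h.identity >= min_identity:
                    found.append(h)
            if len(found) >= max_hits_per_read:
                break
        # one best hit per claimed read region; de-duplicate across consensi
        found.sort(key=lambda h: (-h.identity, h.consensus_id))
        kept: list[Hit] = []
        for h in found:
            if all(h.read_end < k.read_start or h.read_start > k.read_end for k in kept):
                kept.append(h)
            if len(kept) >= max_hits_per_read:
                break
        hits.extend(kept)
    return hits


def divergence(hit: Hit, mask: CpGMask, consensus: ConsensusSequence) -> float:
    """CpG-masked percent divergence of a hit from its consensus.

    Over consensus columns within the hit's span, masked columns and gap
    columns are excluded; divergence = 100 * mismatches / retained columns.
    """
    q = encode(consensus.sequence)
    ci = hit.pairs[:, 0]
    ri = hit.pairs[:, 1]
    aligned = (ci >= 0) & (ri >= 0)
    ci, ri = ci[aligned], ri[aligned]
    masked = mask.as_bool(len(consensus.sequence))
    keep = ~masked[ci]
    ci, ri = ci[keep], ri[keep]
    n = len(ci)
    if n == 0:
        raise ValueError("zero retained columns: divergence undefined")
    mism = int((q[ci] != hit.read_codes[ri]).sum())
    return 100.0 * mism / n


@dataclass
class AssignmentTable:
    """Per-read subfamily assignments plus normalization denominators."""

    table: pd.DataFrame  # read_id, species, subfamily_id, divergence_cpg_masked, coverage
    total_bp: dict[str, int] = field(default_factory=dict)


def assign(hits: list[Hit], subfamilies, total_bp: dict[str, int] | None = None) -> AssignmentTable:
    """Assign each hit to the minimum-divergence subfamily.

    ``subfamilies`` supplies finalized consensi sharing one column frame (each
    must have ``consensus`` text, ``core_start`` frame offset, ``cpg`` mask and
    ``subfamily_id``).  Ties break to higher coverage, then earlier
    subfamily_id.  One assignment per hit.
    """
    subs = list(subfamilies)
    if not subs:
        raise ValueError("no subfamilies to assign to")
    cons_codes = [encode(s.consensus) for s in subs]
    cons_mask = [s.cpg.as_bool(len(s.consensus)) for s in subs]
    rows = []
    for h in hits:
        # project hit into the shared frame using its own consensus's offset
        src = next(s for s in subs if s.subfamily_id == h.consensus_id)
        L_frame = max(s.core_start - 1 + len(s.consensus) for s in subs)
        row = np.full(L_frame, GAP_CODE, dtype=np.uint8)
        proj = h.consensus_row(len(src.consensus))
        row[src.core_start - 1 : src.core_start - 1 + len(src.consensus)] = proj
        best = None
        for j, s in enumerate(subs):
            span = row[s.core_start - 1 : s.core_start - 1 + len(s.consensus)]
            valid = (span != GAP_CODE) & ~cons_mask[j]
            n = int(valid.sum())
            if n == 0:
                continue
            mism = int((span[valid] != cons_codes[j][valid]).sum())
            div = 100.0 * mism / n
            cov = 100.0 * n / len(s.consensus)
            key = (round(div, 9), -cov, s.subfamily_id)
            if best is None or key < best[0]:
                best = (key, s.subfamily_id, div, cov)
        if best is not None:
            rows.append(
                dict(
                    read_id=h.read_id,
                    species=h.species,
                    subfamily_id=best[1],
                    divergence_cpg_masked=best[2],
                    coverage=best[3],
                )
            )
    table = pd.DataFrame(
        rows, columns=["read_id", "species", "subfamily_id", "divergence_cpg_masked", "coverage"]
    )
    return AssignmentTable(table=table, total_bp=dict(total_bp or {}))
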