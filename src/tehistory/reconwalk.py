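"""Iterative consensus reconstruction ("walk") from unassembled reads.

Starting from a seed consensus, each round recruits reads that align to the
current consensus at or above an identity cutoff and overhang the growing end
by at least ``min_overhang`` bases, column-aligns the overhangs at their
junction with the consensus, and appends the majority base of every
sufficiently supported column, up to ``extension_step`` bases per round.  The
walk stops when no column is supported (``no_support``), when the consensus
reaches ``max_length``, or -- in the 3' direction -- when the appended
sequence ends in a poly-A run of >= 10 bases (``polyA``), the natural end of
a LINE.

High identity cutoffs (97-99%) restrict recruitment to the most recently
active copies and so reconstruct the young master; lower cutoffs (~92%)
admit older copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import KmerIndex, kmer_candidates, smith_waterman
from .seqio import ReadSet, encode, decode, revcomp

POLYA_RUN = 10


@dataclass
class WalkParams:
    identity_cutoff: float = 97.0
    min_overhang: int = 100
    min_support: int = 3
    extension_step: int = 100
    direction: str = "3prime"  # {3prime, 5prime, both}
    max_length: int = 10_000
    min_agreement: float = 0.6
    end_slack: int = 5  # alignment may stop this close to the consensus end
    prefilter_k: int = 12
    prefilter_min_shared: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.identity_cutoff <= 100):
            raise ValueError("identity_cutoff must be in (0, 100]")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2")
        if self.direction not in ("3prime", "5prime", "both"):
            raise ValueError("direction must be 3prime, 5prime or both")


@dataclass
class RoundAudit:
    round_index: int
    direction: str
    reads_recruited: int
    bases_added: int
    support: list[int] = field(default_factory=list)


@dataclass
class WalkResult:
    final_consensus: str
    rounds: list[RoundAudit]
    stop_reason: str  # no_support | max_length | polyA


def percent_identity(a: str, b: str) -> float:
    """Identity over two equal-length aligned strings.

    100 * matches / (matches + mismatches + gap columns); symmetric.  Columns
    gapped on either side count in the denominator.
    """
    if len(a) != len(b):
        raise ValueError("aligned regions must have equal length")
    if len(a) == 0:
        raise ValueError("zero aligned columns: identity undefined")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-" and x != "N")
    return 100.0 * matches / len(a)


def _alignment_identity(aln, q_codes, t_codes) -> float:
    """Identity of a LocalAlignment over its full aligned span, gaps penalized."""
    qi = aln.pairs[:, 0]
    ti = aln.pairs[:, 1]
    both = (qi >= 0) & (ti >= 0)
    matches = int(
        ((q_codes[qi[both]] == t_codes[ti[both]]) & (q_codes[qi[both]] < 4)).sum()
    )
    return 100.0 * matches / aln.n_columns


def _extend_3prime(
    consensus: str, reads: list[tuple[str, str]], params: WalkParams
) -> tuple[str, RoundAudit, bool]:
    """One 3' extension round; returns (new consensus, audit, hit_polyA)."""
    L = len(consensus)
    cons_codes = encode(consensus)
    index = KmerIndex([consensus], k=params.prefilter_k)
    cands = kmer_candidates(reads, index, min_shared=params.prefilter_min_shared)
    overhangs: list[np.ndarray] = []
    recruited = 0
    for i, strand in cands:
        seq = reads[i][1] if strand == "+" else revcomp(reads[i][1])
        codes = encode(seq)
        aln = smith_waterman(cons_codes, codes)
        if aln is None:
            continue
        if _alignment_identity(aln, cons_codes, codes) < params.identity_cutoff:
            continue
        # must reach (close to) the growing 3' end of the consensus
        if aln.query_end < L - params.end_slack:
            continue
        # overhang: read sequence past the aligned end, shifted by how far the
        # alignment stopped short of the consensus end
        gap_to_end = L - aln.query_end
        tail = codes[aln.target_end + gap_to_end :]
        if len(tail) < params.min_overhang:
            continue
        overhangs.append(tail)
        recruited += 1

    appended: list[int] = []
    support: list[int] = []
    hit_polya = False
    step = min(params.extension_step, params.max_length - L)
    for col in range(step):
        bases = [o[col] for o in overhangs if col < len(o) and o[col] < 4]
        if len(bases) < params.min_support:
            break
        counts = np.bincount(bases, minlength=4)
        best = int(np.argmax(counts))  # argmax ties break A<C<G<T
        if counts[best] < params.min_agreement * len(bases):
            break
        appended.append(best)
        support.append(len(bases))
        if len(appended) >= POLYA_RUN and all(b == 0 for b in appended[-POLYA_RUN:]):
            hit_polya = True
            break
    new_consensus = consensus + decode(np.array(appended, dtype=np.uint8)) if appended else consensus
    audit = RoundAudit(0, "3prime", recruited, len(appended), support)
    return new_consensus, audit, hit_polya


def walk(seed: str, reads: ReadSet, params: WalkParams) -> WalkResult:
    """Grow a seed consensus through read overhangs until a stop condition.

    5' extension is handled by walking the reverse complement 3'-wards (the
    poly-A stop applies only to true 3' extension).
    """
    if len(seed) < 50:
        raise ValueError("seed must be >= 50 bp")
    if not set(seed) <= set("ACGT"):
        raise ValueError("seed alphabet must be ACGT")
    read_list = list(reads.reads)

    consensus = seed
    rounds: list[RoundAudit] = []
    stop = "no_support"
    directions = {"3prime": ["3prime"], "5prime": ["5prime"], "both": ["3prime", "5prime"]}[
        params.direction
    ]
    active = set(directions)
    rnum = 0
    while active:
        if len(consensus) >= params.max_length:
            stop = "max_length"
            break
        progressed = False
        for d in list(active):
            if d == "3prime":
                new, audit, polya = _extend_3prime(consensus, read_list, params)
            else:
                rc_reads = [(rid, revcomp(s)) for rid, s in read_list]
                new_rc, audit, _ = _extend_3prime(revcomp(consensus), rc_reads, params)
                new, polya = revcomp(new_rc), False
                audit.direction = "5prime"
            rnum += 1
            audit.round_index = rnum
            rounds.append(audit)
            if polya:
                active.discard(d)
                stop = "polyA"
            if len(new) == len(consensus):
                active.discard(d)
            else:
                progressed = True
            consensus = new
            if len(consensus) >= params.max_length:
                active.clear()
                stop = "max_length"
                break
        if not progressed and stop not in ("polyA", "max_length"):
            stop = "no_support"
            break
    if not rounds:
        # degenerate cap: max_length already reached by the seed itself
        stop = "max_length" if len(seed) >= params.max_length else "no_support"
    return WalkResult(final_consensus=consensus, rounds=rounds, stop_reason=stop)
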