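"""Subfamily discovery from shared, co-segregating sequence variants.

Element copies descended from the same master share the private substitutions
of that master; copies from different masters do not.  The partitioner
therefore looks for *pairs* of column variants that co-occur far more often
than independence predicts, splits off the carriers of the best such pair,
re-polishes membership by nearest-consensus reassignment, and recurses.  A
minimum subfamily size guards against noise: with independent per-copy
mutations the expected joint count of two unrelated variants is
m_i * m_j / N, far below any realistic size floor.

CpG columns of the current consensus are excluded both as candidate
diagnostic sites and from nearest-consensus distances: methylation-driven
hypermutation makes CpG sites recurrently homoplastic, so they carry no
reliable descent signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copyassign import ConsensusSequence, Hit, search
from .seqio import AnchoredAlignment, CpGMask, ReadSet, cpg_mask, decode, encode

GAP_CODE = 4


@dataclass
class DiagnosticPair:
    """Two co-segregating column variants relative to the current consensus."""

    col_i: int
    base_i: str
    col_j: int
    base_j: str
    joint_count: int
    expected_count: float


@dataclass
class CosegParams:
    min_subfamily_size: int = 250
    enrichment_factor: float = 1.5
    max_rounds: int = 100
    reassignment_convergence: int = 10

    def __post_init__(self) -> None:
        if self.min_subfamily_size < 2:
            raise ValueError("min_subfamily_size must be >= 2")
        if self.enrichment_factor <= 1:
            raise ValueError("enrichment_factor must be > 1")


@dataclass
class Subfamily:
    """A discovered subfamily: consensus over its covered core, members per species."""

    subfamily_id: str
    consensus: str
    core_start: int  # 1-based frame column of consensus[0]
    members: dict[str, list[str]] = field(default_factory=dict)
    defining_pairs: list[DiagnosticPair] = field(default_factory=list)
    cpg: CpGMask | None = None
    element: str = ""

    @property
    def core_end(self) -> int:
        return self.core_start + len(self.consensus) - 1

    @property
    def size_by_species(self) -> dict[str, int]:
        return {sp: len(ids) for sp, ids in self.members.items()}

    @property
    def size(self) -> int:
        return sum(len(ids) for ids in self.members.values())


# ---------------------------------------------------------------------------
# anchored alignment construction


def build_anchored_alignment(hits: list[Hit], consensus: ConsensusSequence) -> AnchoredAlignment:
    """Project hits onto the column frame of one consensus (one row per hit)."""
    L = len(consensus.sequence)
    rows = np.full((len(hits), L), GAP_CODE, dtype=np.uint8)
    ids, species = [], []
    for i, h in enumerate(hits):
        if h.consensus_id != consensus.consensus_id:
            raise ValueError(f"hit {h.read_id} references consensus {h.consensus_id!r}")
        if not (1 <= h.consensus_start <= h.consensus_end <= L):
            raise ValueError(f"hit {h.read_id}: coordinates outside consensus")
        rows[i] = h.consensus_row(L)
        ids.append(h.read_id)
        species.append(h.species)
    return AnchoredAlignment(
        consensus_id=consensus.consensus_id, columns=L, matrix=rows, row_ids=ids, row_species=species
    )


def project_hits_to_frame(
    hits: list[Hit],
    library: list[ConsensusSequence],
    frame_columns: int,
    frame_id: str = "frame",
) -> AnchoredAlignment:
    """Project hits against any library consensus into the shared frame.

    Library consensi must be anchored (``frame_start``) in one coordinate
    frame; each hit is projected through the consensus it was aligned to.
    """
    by_id = {c.consensus_id: c for c in library}
    rows = np.full((len(hits), frame_columns), GAP_CODE, dtype=np.uint8)
    ids, species = [], []
    for i, h in enumerate(hits):
        c = by_id[h.consensus_id]
        local = h.consensus_row(len(c.sequence))
        s = c.frame_start - 1
        e = min(s + len(c.sequence), frame_columns)
        rows[i, s:e] = local[: e - s]
        ids.append(h.read_id)
        species.append(h.species)
    return AnchoredAlignment(
        consensus_id=frame_id, columns=frame_columns, matrix=rows, row_ids=ids, row_species=species
    )


# ---------------------------------------------------------------------------
# core partitioning


def _majority(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column majority base (ties A<C<G<T) and base coverage counts."""
    counts = np.stack([(M == b).sum(axis=0) for b in range(4)])
    return counts.argmax(axis=0).astype(np.uint8), counts.sum(axis=0)


def _covered_interval(M: np.ndarray) -> tuple[int, int] | None:
    """0-based [start, end) interval of columns with non-gap majority."""
    cov = (M < 4).sum(axis=0)
    good = np.flatnonzero(cov * 2 >= M.shape[0])
    if len(good) == 0:
        return None
    return int(good[0]), int(good[-1]) + 1


def find_best_pair(
    M: np.ndarray, params: CosegParams
) -> tuple[DiagnosticPair, np.ndarray] | None:
    """Best qualifying diagnostic pair of the alignment block, or None.

    Qualifying: joint_count >= min size, remainder >= min size, and
    joint_count >= enrichment_factor * (m_i * m_j / N).  The returned mask
    selects the carrier rows of both variants.  Deterministic: highest joint
    count wins, ties resolved by ascending (col_i, col_j, base_i, base_j).
    """
    n = M.shape[0]
    cons, _ = _majority(M)
    cpg_cols = np.zeros(M.shape[1], dtype=bool)
    is_cg = (cons[:-1] == 1) & (cons[1:] == 2)
    cpg_cols[:-1] |= is_cg
    cpg_cols[1:] |= is_cg

    cand_cols: list[int] = []
    cand_bases: list[int] = []
    for col in np.flatnonzero(~cpg_cols):
        colvals = M[:, col]
        for base in range(4):
            if base == cons[col]:
                continue
            if int((colvals == base).sum()) >= params.min_subfamily_size:
                cand_cols.append(col)
                cand_bases.append(base)
    if len(cand_cols) < 2:
        return None
    B = np.stack([M[:, c] == b for c, b in zip(cand_cols, cand_bases)], axis=1)
    m = B.sum(axis=0).astype(np.float64)
    J = B.astype(np.float32).T @ B.astype(np.float32)
    J = J.astype(np.int64)
    K = len(cand_cols)
    cols = np.asarray(cand_cols)
    ok = (
        (J >= params.min_subfamily_size)
        & (J <= n - params.min_subfamily_size)
        & (J.astype(np.float64) >= params.enrichment_factor * np.outer(m, m) / n)
        & (cols[:, None] < cols[None, :])
    )
    if not ok.any():
        return None
    best_j = J[ok].max()
    cand_idx = np.argwhere(ok & (J == best_j))
    # deterministic tie-break
    keys = sorted(
        (cols[k], cols[l], cand_bases[k], cand_bases[l], k, l) for k, l in cand_idx
    )
    _, _, _, _, k, l = keys[0]
    pair = DiagnosticPair(
        col_i=int(cols[k]) + 1,
        base_i="ACGT"[cand_bases[k]],
        col_j=int(cols[l]) + 1,
        base_j="ACGT"[cand_bases[l]],
        joint_count=int(J[k, l]),
        expected_count=float(m[k] * m[l] / n),
    )
    return pair, B[:, k] & B[:, l]


def _distance_to(M: np.ndarray, cons: np.ndarray, valid_cols: np.ndarray) -> np.ndarray:
    """Per-row mismatch count vs a consensus over valid, non-gap columns."""
    sub = M[:, valid_cols]
    return ((sub != cons[valid_cols][None, :]) & (sub < 4)).sum(axis=1)


def detect_subfamilies(aln: AnchoredAlignment, params: CosegParams) -> list[Subfamily]:
    """Greedy recursive bipartition on co-segregating variants.

    Returns an exhaustive, disjoint partition of the alignment rows; if no
    qualifying diagnostic pair exists (or there are fewer rows than the size
    floor) a single subfamily is returned.
    """
    M = aln.matrix
    n = M.shape[0]
    splits_left = [params.max_rounds]
    leaves: list[tuple[np.ndarray, DiagnosticPair | None]] = []

    def recurse(idx: np.ndarray, pair_from: DiagnosticPair | None) -> None:
        block = M[idx]
        if len(idx) < 2 * params.min_subfamily_size or splits_left[0] <= 0:
            leaves.append((idx, pair_from))
            return
        found = find_best_pair(block, params)
        if found is None:
            leaves.append((idx, pair_from))
            return
        pair, in_new = found
        splits_left[0] -= 1
        # nearest-consensus reassignment until stable
        cons_all, _ = _majority(block)
        cpg_cols = np.zeros(block.shape[1], dtype=bool)
        is_cg = (cons_all[:-1] == 1) & (cons_all[1:] == 2)
        cpg_cols[:-1] |= is_cg
        cpg_cols[1:] |= is_cg
        valid = ~cpg_cols
        for _ in range(params.reassignment_convergence):
            if in_new.sum() == 0 or in_new.sum() == len(idx):
                break
            cons1, _ = _majority(block[in_new])
            cons0, _ = _majority(block[~in_new])
            d1 = _distance_to(block, cons1, valid)
            d0 = _distance_to(block, cons0, valid)
            new_in = d1 < d0  # ties go to the earlier-created (remainder) side
            if (new_in == in_new).all():
                break
            in_new = new_in
        n_new = int(in_new.sum())
        if n_new < params.min_subfamily_size or len(idx) - n_new < params.min_subfamily_size:
            leaves.append((idx, pair_from))
            return
        recurse(idx[~in_new], pair_from)
        recurse(idx[in_new], pair)

    recurse(np.arange(n), None)

    subfamilies: list[Subfamily] = []
    for i, (idx, pair) in enumerate(leaves, start=1):
        block = M[idx]
        interval = _covered_interval(block)
        if interval is None:
            continue
        s, e = interval
        cons, _ = _majority(block[:, s:e])
        members: dict[str, list[str]] = {}
        for r in idx:
            members.setdefault(aln.row_species[r], []).append(aln.row_ids[r])
        subfamilies.append(
            Subfamily(
                subfamily_id=f"{aln.consensus_id}_s{i:02d}",
                consensus=decode(cons),
                core_start=s + 1,
                members=members,
                defining_pairs=[pair] if pair else [],
            )
        )
    return subfamilies


def finalize_consensi(subfamilies: list[Subfamily]) -> list[Subfamily]:
    """Trim all consensi to the column interval covered by every subfamily and
    attach CpG masks (masked columns are excluded from divergence downstream)."""
    if not subfamilies:
        raise ValueError("no subfamilies to finalize")
    start = max(s.core_start for s in subfamilies)
    end = min(s.core_end for s in subfamilies)
    if end < start + 1:
        raise ValueError(
            "empty common core across subfamilies; increase the minimum overlap "
            "or lower coverage requirements"
        )
    out = []
    for s in subfamilies:
        lo = start - s.core_start
        hi = end - s.core_start + 1
        trimmed = s.consensus[lo:hi]
        out.append(
            Subfamily(
                subfamily_id=s.subfamily_id,
                consensus=trimmed,
                core_start=start,
                members=s.members,
                defining_pairs=s.defining_pairs,
                cpg=cpg_mask(trimmed, s.subfamily_id),
                element=s.element,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the two-round protocol


def two_round_protocol(
    readsets: dict[str, ReadSet],
    seed_consensus: ConsensusSequence,
    round1: CosegParams,
    round2: CosegParams,
    element: str = "",
    min_identity: float = 60.0,
    min_coverage: float = 90.0,
    search_kwargs: dict | None = None,
) -> tuple[list[Subfamily], dict]:
    """Two-round, threshold-escalating subfamily discovery.

    Round 1 runs per species on hits to the seed consensus; round 2 pools
    both species' hits against all round-1 subfamily consensi (so older
    subfamilies, reachable only from round-1 consensi, are found) and applies
    the possibly escalated round-2 size floor.  Returned subfamilies are
    core-trimmed and CpG-masked.
    """
    kw = dict(search_kwargs or {})
    frame_len = len(seed_consensus.sequence)
    trace: dict = {
        "element": element,
        "round1_min_size": round1.min_subfamily_size,
        "round2_min_size": round2.min_subfamily_size,
        "round1_subfamilies": {},
    }

    library: list[ConsensusSequence] = []
    for sp in sorted(readsets):
        hits = search(readsets[sp], [seed_consensus], min_identity, min_coverage, **kw)
        if not hits:
            continue
        aln = build_anchored_alignment(hits, seed_consensus)
        subs = detect_subfamilies(aln, round1)
        trace["round1_subfamilies"][sp] = len(subs)
        for s in subs:
            library.append(
                ConsensusSequence(
                    consensus_id=f"{element}_{sp}_{s.subfamily_id}",
                    sequence=s.consensus,
                    frame_start=s.core_start,
                )
            )
    if not library:
        library = [seed_consensus]

    hits2: list[Hit] = []
    for sp in sorted(readsets):
        hits2.extend(search(readsets[sp], library, min_identity, min_coverage, **kw))
    aln2 = project_hits_to_frame(hits2, library, frame_len, frame_id=element or "frame")
    subs2 = detect_subfamilies(aln2, round2)
    for s in subs2:
        s.element = element
    trace["round2_subfamilies"] = len(subs2)
    return finalize_consensi(subs2), trace
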