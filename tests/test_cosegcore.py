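import numpy as np
import pytest

from tehistory.copyassign import ConsensusSequence
from tehistory.cosegcore import (
    CosegParams,
    Subfamily,
    build_anchored_alignment,
    detect_subfamilies,
    finalize_consensi,
    find_best_pair,
    two_round_protocol,
)
from tehistory.seqio import AnchoredAlignment, decode, encode
from tests.conftest import make_gapfree_hit


def _aln_from_matrix(M, species=None):
    n = M.shape[0]
    return AnchoredAlignment(
        consensus_id="c",
        columns=M.shape[1],
        matrix=M.astype(np.uint8),
        row_ids=[f"r{i}" for i in range(n)],
        row_species=species or ["sp"] * n,
    )


def _noisy_rows(master, n, noise, rng):
    M = np.tile(master, (n, 1))
    hit = rng.random(M.shape) < noise
    M[hit] = (M[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return M


class TestBuildAnchoredAlignment:
    def test_perfect_hit_row_equals_read(self):
        cons = ConsensusSequence("c", "ACGTACGTAC")
        h = make_gapfree_hit(cons.sequence, "ACGTACGTAC")
        aln = build_anchored_alignment([h], cons)
        assert decode(aln.matrix[0]) == "ACGTACGTAC"

    def test_partial_hit_has_leading_gaps(self):
        cons = ConsensusSequence("c", "A" * 300)
        h = make_gapfree_hit(cons.sequence, "A" * 250, offset=50)
        aln = build_anchored_alignment([h], cons)
        row = decode(aln.matrix[0])
        assert row[:50] == "-" * 50 and row[50:] == "A" * 250

    def test_read_insertion_dropped_row_length_constant(self):
        cons = ConsensusSequence("c", "ACGTACGTAC")
        # read has a 2 bp insertion between consensus cols 5 and 6
        pairs = [(i, i) for i in range(5)] + [(-1, 5), (-1, 6)] + [(i, i + 2) for i in range(5, 10)]
        h = make_gapfree_hit(cons.sequence, "ACGTATTCGTAC")
        h.pairs = np.array(pairs, dtype=np.int32)
        h.consensus_start, h.consensus_end = 1, 10
        aln = build_anchored_alignment([h], cons)
        assert aln.matrix.shape == (1, 10)
        assert decode(aln.matrix[0]) == "ACGTACGTAC"

    def test_out_of_bounds_hit_rejected(self):
        cons = ConsensusSequence("c", "ACGT" * 5)
        h = make_gapfree_hit(cons.sequence, "ACGT")
        h.consensus_end = 99
        with pytest.raises(ValueError):
            build_anchored_alignment([h], cons)


class TestDetectSubfamilies:
    def test_two_planted_bursts_recovered(self):
        rng = np.random.default_rng(21)
        L = 100
        m1 = rng.integers(0, 4, L)
        m2 = m1.copy()
        diag = rng.choice(L, 6, replace=False)
        m2[diag] = (m2[diag] + 1) % 4
        M = np.vstack([_noisy_rows(m1, 600, 0.02, rng), _noisy_rows(m2, 600, 0.02, rng)])
        subs = detect_subfamilies(_aln_from_matrix(M), CosegParams(min_subfamily_size=250))
        assert len(subs) == 2
        # each consensus within 1 mismatch of its planted master
        recovered = [encode(s.consensus) for s in subs]
        d = np.array([[int((r != m).sum()) for m in (m1, m2)] for r in recovered])
        assert d.min(axis=1).max() <= 1
        assert set(d.argmin(axis=1)) == {0, 1}
        # membership accuracy
        truth = np.array([0] * 600 + [1] * 600)
        ids = {f"r{i}": truth[i] for i in range(1200)}
        correct = 0
        for s, m in zip(subs, d.argmin(axis=1)):
            correct += sum(1 for rid in s.members["sp"] if ids[rid] == m)
        assert correct / 1200 >= 0.95

    def test_independent_noise_is_one_subfamily(self):
        rng = np.random.default_rng(22)
        master = rng.integers(0, 4, 80)
        M = _noisy_rows(master, 600, 0.10, rng)
        subs = detect_subfamilies(
            _aln_from_matrix(M), CosegParams(min_subfamily_size=250, enrichment_factor=5)
        )
        assert len(subs) == 1

    def test_below_size_floor_stays_merged(self):
        rng = np.random.default_rng(23)
        L = 100
        m1 = rng.integers(0, 4, L)
        m2 = m1.copy()
        m2[:6] = (m2[:6] + 1) % 4
        M = np.vstack([_noisy_rows(m1, 200, 0.02, rng), _noisy_rows(m2, 200, 0.02, rng)])
        subs = detect_subfamilies(_aln_from_matrix(M), CosegParams(min_subfamily_size=250))
        assert len(subs) == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(24)
        m1 = rng.integers(0, 4, 60)
        m2 = m1.copy()
        m2[:5] = (m2[:5] + 2) % 4
        M = np.vstack([_noisy_rows(m1, 40, 0.03, rng), _noisy_rows(m2, 40, 0.03, rng)])
        subs = detect_subfamilies(_aln_from_matrix(M), CosegParams(min_subfamily_size=10))
        all_ids = [rid for s in subs for rid in s.members["sp"]]
        assert len(all_ids) == 80 and len(set(all_ids)) == 80

    def test_deterministic(self):
        rng = np.random.default_rng(25)
        m1 = rng.integers(0, 4, 60)
        m2 = (m1 + 1) % 4
        M = np.vstack([_noisy_rows(m1, 30, 0.05, rng), _noisy_rows(m2, 30, 0.05, rng)])
        a = detect_subfamilies(_aln_from_matrix(M), CosegParams(min_subfamily_size=10))
        b = detect_subfamilies(_aln_from_matrix(M), CosegParams(min_subfamily_size=10))
        assert [s.members for s in a] == [s.members for s in b]
        assert [s.consensus for s in a] == [s.consensus for s in b]


def brute_force_best_pair(M, min_size, factor):
    """Exhaustive enumeration oracle for the diagnostic-pair choice."""
    n, L = M.shape
    counts = np.stack([(M == b).sum(axis=0) for b in range(4)])
    cons = counts.argmax(axis=0)
    cpg = np.zeros(L, bool)
    is_cg = (cons[:-1] == 1) & (cons[1:] == 2)
    cpg[:-1] |= is_cg
    cpg[1:] |= is_cg
    variants = [
        (c, b)
        for c in range(L)
        if not cpg[c]
        for b in range(4)
        if b != cons[c] and (M[:, c] == b).sum() >= min_size
    ]
    best = None
    for i in range(len(variants)):
        for j in range(i + 1, len(variants)):
            (c1, b1), (c2, b2) = variants[i], variants[j]
            if c1 == c2:
                continue
            if c1 > c2:
                (c1, b1), (c2, b2) = (c2, b2), (c1, b1)
            carriers = (M[:, c1] == b1) & (M[:, c2] == b2)
            joint = int(carriers.sum())
            m1 = int((M[:, c1] == b1).sum())
            m2 = int((M[:, c2] == b2).sum())
            if joint < min_size or joint > n - min_size:
                continue
            if joint < factor * m1 * m2 / n:
                continue
            key = (-joint, c1, c2, b1, b2)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return (best[1] + 1, "ACGT"[best[3]], best[2] + 1, "ACGT"[best[4]], -best[0])


class TestPairOracle:
    def test_best_pair_matches_bruteforce_on_small_alignments(self):
        rng = np.random.default_rng(26)
        params = CosegParams(min_subfamily_size=5, enrichment_factor=1.5)
        checked = 0
        for _ in range(50):
            n = int(rng.integers(12, 50))
            L = int(rng.integers(8, 20))
            master = rng.integers(0, 4, L)
            M = _noisy_rows(master, n, 0.1, rng)
            if rng.random() < 0.6:  # plant a co-segregating group
                k = int(rng.integers(5, max(6, n // 2)))
                cols = rng.choice(L, 2, replace=False)
                M[:k, cols] = (master[cols] + 1) % 4
            got = find_best_pair(M, params)
            want = brute_force_best_pair(M, 5, 1.5)
            if want is None:
                assert got is None
            else:
                pair, _ = got
                assert (pair.col_i, pair.base_i, pair.col_j, pair.base_j, pair.joint_count) == want
                checked += 1
        assert checked >= 10


class TestFinalize:
    def _sub(self, sid, cons, start):
        return Subfamily(subfamily_id=sid, consensus=cons, core_start=start, members={"sp": ["x" + sid]})

    def test_trims_to_common_interval(self):
        a = self._sub("a", "A" * 300, 1)       # covers 1-300
        b = self._sub("b", "C" * 290, 11)      # covers 11-300
        out = finalize_consensi([a, b])
        assert all(s.core_start == 11 and s.core_end == 300 for s in out)
        assert all(len(s.consensus) == 290 for s in out)

    def test_identical_coverage_is_identity(self):
        a = self._sub("a", "ACGT" * 25, 5)
        b = self._sub("b", "TGCA" * 25, 5)
        out = finalize_consensi([a, b])
        assert out[0].consensus == a.consensus and out[0].core_start == 5

    def test_masks_attached(self):
        a = self._sub("a", "TTCGTT", 1)
        out = finalize_consensi([a])
        assert set(out[0].cpg.masked_columns) == {3, 4}

    def test_empty_common_core_is_error(self):
        a = self._sub("a", "A" * 50, 1)     # 1-50
        b = self._sub("b", "C" * 50, 100)   # 100-149
        with pytest.raises(ValueError):
            finalize_consensi([a, b])


class TestTwoRoundProtocol:
    def test_recovers_bursts_and_records_escalated_floors(self, two_burst_sim):
        cfg, readsets, truth, masters = two_burst_sim
        seed = ConsensusSequence("seed", masters["young"])
        subs, trace = two_round_protocol(
            {"species_B": readsets["species_B"]},
            seed,
            CosegParams(min_subfamily_size=100),
            CosegParams(min_subfamily_size=150),
            element="E",
        )
        assert (trace["round1_min_size"], trace["round2_min_size"]) == (100, 150)
        assert len(subs) == 2
        assert all(set(s.members) <= {"species_B"} for s in subs)
        # members map back to the planted bursts
        burst_of = dict(zip(truth.copy_id, truth.burst_id))
        for s in subs:
            bursts = [burst_of[rid.rsplit("_r", 1)[0].replace("species_B_", "")] for rid in s.members["species_B"]]
            top = max(set(bursts), key=bursts.count)
            assert bursts.count(top) / len(bursts) >= 0.95

    def test_sine_style_floor_escalation_trace(self, two_burst_sim):
        cfg, readsets, _, masters = two_burst_sim
        seed = ConsensusSequence("seed", masters["young"])
        subs, trace = two_round_protocol(
            {"species_B": readsets["species_B"]},
            seed,
            CosegParams(min_subfamily_size=1000),
            CosegParams(min_subfamily_size=2000),
            element="E",
        )
        assert (trace["round1_min_size"], trace["round2_min_size"]) == (1000, 2000)
        assert len(subs) == 1  # 600 copies sit below the SINE floors
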