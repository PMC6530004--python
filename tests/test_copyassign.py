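import numpy as np
import pytest

from tehistory.copyassign import ConsensusSequence, assign, divergence, search
from tehistory.cosegcore import Subfamily
from tehistory.seqio import CpGMask, ReadSet, cpg_mask, decode, encode, revcomp
from tehistory.simkit import ElementModel, _random_master, evolve_master
from tests.conftest import make_gapfree_hit


def _consensus(length=300, seed=31):
    rng = np.random.default_rng(seed)
    return decode(_random_master(ElementModel("E", length), rng))


class TestSearch:
    def test_exact_read_full_hit(self):
        c = ConsensusSequence("c", _consensus())
        rs = ReadSet("sp", [("r1", c.sequence)])
        hits = search(rs, [c])
        assert len(hits) == 1
        h = hits[0]
        assert h.query_coverage == 100.0 and h.identity == 100.0 and h.strand == "+"
        assert divergence(h, cpg_mask(c.sequence), c) == 0.0

    def test_reverse_complement_hits_minus_strand(self):
        c = ConsensusSequence("c", _consensus(seed=32))
        rs = ReadSet("sp", [("r1", revcomp(c.sequence))])
        hits = search(rs, [c])
        assert len(hits) == 1 and hits[0].strand == "-"
        assert divergence(hits[0], cpg_mask(c.sequence), c) == 0.0

    def test_coverage_filter_drops_partial_hit(self):
        c = ConsensusSequence("c", _consensus(seed=33))  # 300 columns
        rs = ReadSet("sp", [("r1", c.sequence[:260])])   # 86.7% coverage
        assert search(rs, [c], min_coverage=90.0) == []
        assert len(search(rs, [c], min_coverage=80.0)) == 1

    def test_background_read_yields_nothing(self):
        rng = np.random.default_rng(34)
        c = ConsensusSequence("c", _consensus(seed=35))
        bg = decode(rng.integers(0, 4, 500).astype(np.uint8))
        assert search(ReadSet("sp", [("r1", bg)]), [c]) == []

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            search(ReadSet("sp", []), [])


class TestDivergence:
    def test_mismatch_at_masked_column_not_counted(self):
        c = ConsensusSequence("c", "AACGTT")
        mask = cpg_mask(c.sequence)  # columns {3, 4}
        assert set(mask.masked_columns) == {3, 4}
        h = make_gapfree_hit(c.sequence, "AATGTT")
        assert divergence(h, mask, c) == 0.0

    def test_unmasked_mismatch_counted_over_retained_columns(self):
        c = ConsensusSequence("c", "AACGTT")
        h = make_gapfree_hit(c.sequence, "TACGTT")
        assert divergence(h, cpg_mask(c.sequence), c) == 25.0

    def test_identical_read_zero_for_any_mask(self):
        c = ConsensusSequence("c", "ACGTACGTACGT")
        h = make_gapfree_hit(c.sequence, c.sequence)
        for cols in [frozenset(), frozenset({1, 2}), frozenset({5, 6, 7, 8})]:
            assert divergence(h, CpGMask("c", cols), c) == 0.0

    def test_zero_retained_columns_is_error(self):
        c = ConsensusSequence("c", "ACGT")
        h = make_gapfree_hit(c.sequence, "ACGT")
        with pytest.raises(ValueError):
            divergence(h, CpGMask("c", frozenset({1, 2, 3, 4})), c)

    def test_gapfree_divergence_equals_hamming_oracle(self):
        # on substitution-only copies, divergence must equal the mismatch
        # fraction over unmasked columns exactly
        rng = np.random.default_rng(36)
        elem = ElementModel("E", 120)
        master = decode(_random_master(elem, rng))
        mask = cpg_mask(master)
        masked = mask.as_bool(120)
        c = ConsensusSequence("c", master)
        for _ in range(30):
            copy = evolve_master(master, 12.0, elem, rng)
            h = make_gapfree_hit(master, copy)
            want = 100.0 * sum(
                1 for i in range(120) if not masked[i] and copy[i] != master[i]
            ) / int((~masked).sum())
            assert divergence(h, mask, c) == want


def _sub(sid, cons, start=1):
    return Subfamily(subfamily_id=sid, consensus=cons, core_start=start,
                     members={}, cpg=cpg_mask(cons, sid))


class TestAssign:
    def test_argmin_divergence_wins(self):
        x = _sub("sx", "A" * 40)
        y = _sub("sy", "A" * 20 + "C" * 20)
        read = "A" * 38 + "CC"  # 5% from x, 45% from y
        h = make_gapfree_hit(x.consensus, read)
        h.consensus_id = "sx"
        t = assign([h], [x, y]).table
        assert list(t.subfamily_id) == ["sx"]

    def test_divergence_tie_breaks_to_higher_coverage(self):
        x = _sub("sx", "A" * 30)          # frame 1-30
        y = _sub("sy", "A" * 40)          # frame 1-40
        read = "A" * 30                   # 0% from both; covers 100% of x, 75% of y
        h = make_gapfree_hit(x.consensus, read)
        h.consensus_id = "sx"
        t = assign([h], [x, y]).table
        assert list(t.subfamily_id) == ["sx"]

    def test_exact_tie_breaks_to_earlier_id(self):
        a = _sub("sa", "A" * 30)
        b = _sub("sb", "A" * 30)
        h = make_gapfree_hit(a.consensus, "A" * 30)
        h.consensus_id = "sb"
        t = assign([h], [b, a]).table
        assert list(t.subfamily_id) == ["sa"]

    def test_total_bp_carried(self):
        x = _sub("sx", "A" * 30)
        h = make_gapfree_hit(x.consensus, "A" * 30)
        h.consensus_id = "sx"
        at = assign([h], [x], total_bp={"sp": 12345})
        assert at.total_bp == {"sp": 12345}


class TestStrandInvariance:
    def test_revcomp_reads_get_same_assignment(self, two_burst_sim):
        cfg, readsets, truth, masters = two_burst_sim
        lib = [
            ConsensusSequence("old", masters["old"]).with_cpg_mask(),
            ConsensusSequence("young", masters["young"]).with_cpg_mask(),
        ]
        subs = [
            _sub("old", masters["old"]),
            _sub("young", masters["young"]),
        ]
        reads = [r for r in readsets["species_B"].reads if "_c000" in r[0]][:40]
        fwd = ReadSet("species_B", reads)
        rev = ReadSet("species_B", [(rid, revcomp(s)) for rid, s in reads])
        t1 = assign(search(fwd, lib), subs).table.set_index("read_id")
        t2 = assign(search(rev, lib), subs).table.set_index("read_id")
        assert set(t1.index) == set(t2.index) and len(t1) >= 30
        for rid in t1.index:
            assert t1.loc[rid, "subfamily_id"] == t2.loc[rid, "subfamily_id"]
            assert t1.loc[rid, "divergence_cpg_masked"] == pytest.approx(
                t2.loc[rid, "divergence_cpg_masked"], abs=1e-9
            )

    def test_assignment_accuracy_against_truth(self, two_burst_sim):
        cfg, readsets, truth, masters = two_burst_sim
        lib = [
            ConsensusSequence("old", masters["old"]).with_cpg_mask(),
            ConsensusSequence("young", masters["young"]).with_cpg_mask(),
        ]
        subs = [_sub("old", masters["old"]), _sub("young", masters["young"])]
        t = assign(search(readsets["species_B"], lib), subs,
                   {"species_B": readsets["species_B"].total_bp}).table
        burst_of = dict(zip(truth.copy_id, truth.burst_id))
        hits = 0
        for rid, sub in zip(t.read_id, t.subfamily_id):
            cid = rid.replace("species_B_", "").rsplit("_r", 1)[0]
            hits += int(burst_of[cid] == sub)
        assert len(t) >= 500
        assert hits / len(t) >= 0.95
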