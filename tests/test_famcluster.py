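import numpy as np
import pytest

from tehistory.cosegcore import Subfamily
from tehistory.famcluster import (
    DistanceMatrix,
    Family,
    brute_force_min_partition,
    cluster_families,
    family_consensus,
    family_distance_matrix,
    family_tree,
    name_families,
    pairwise_distances,
)
from tehistory.seqio import cpg_mask


def _sub(sid, cons, start=1, with_mask=True):
    return Subfamily(
        subfamily_id=sid, consensus=cons, core_start=start, members={},
        cpg=cpg_mask(cons, sid) if with_mask else None,
    )


class TestPairwiseDistances:
    def test_identical_consensi_zero(self):
        dm = pairwise_distances([_sub("a", "ACGTT" * 20), _sub("b", "ACGTT" * 20)])
        assert dm.value("a", "b") == 0.0

    def test_hand_counted_mismatches(self):
        a = "A" * 100
        b = "C" * 3 + "A" * 97
        dm = pairwise_distances([_sub("a", a), _sub("b", b)])
        assert dm.value("a", "b") == 3.0

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(41)
        subs = [
            _sub(f"s{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(5)
        ]
        dm = pairwise_distances(subs)
        assert np.allclose(dm.matrix, dm.matrix.T) and (np.diag(dm.matrix) == 0).all()

    def test_cpg_columns_excluded(self):
        # mismatch hidden inside a CpG of consensus a -> not counted
        a = "TTCGTTTTTT"
        b = "TTTTTTTTTT"
        dm = pairwise_distances([_sub("a", a), _sub("b", b)])
        assert dm.value("a", "b") == 0.0

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([_sub("a", "A" * 10, start=1), _sub("b", "A" * 10, start=3)])


class TestClusterFamilies:
    def _dm(self, d):
        return DistanceMatrix(["A", "B", "C"], np.array(d, dtype=float))

    def test_all_within_threshold_is_one_family(self):
        fams = cluster_families(self._dm([[0, 1, 3], [1, 0, 2], [3, 2, 0]]), 3.5)
        assert [f.subfamily_ids for f in fams] == [["A", "B", "C"]]

    def test_complete_linkage_blocks_distant_member(self):
        fams = cluster_families(self._dm([[0, 1, 4], [1, 0, 2], [4, 2, 0]]), 3.5)
        assert sorted(f.subfamily_ids for f in fams) == [["A", "B"], ["C"]]

    def test_zero_threshold_gives_singletons(self):
        fams = cluster_families(self._dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]]), 0.0)
        assert sorted(f.subfamily_ids for f in fams) == [["A"], ["B"], ["C"]]

    def test_within_family_distances_bounded_by_threshold(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            pts = rng.uniform(0, 15, n)
            d = np.abs(pts[:, None] - pts[None, :])
            dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
            for f in cluster_families(dm, 3.5):
                idx = [dm.labels.index(s) for s in f.subfamily_ids]
                assert all(d[i, j] <= 3.5 for i in idx for j in idx)

    def test_matches_bruteforce_optimum_when_unique(self):
        rng = np.random.default_rng(43)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            pts = np.sort(rng.uniform(0, 20, n))
            d = np.abs(pts[:, None] - pts[None, :])
            dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
            got = sorted(sorted(f.subfamily_ids) for f in cluster_families(dm, 3.5))
            want, unique = brute_force_min_partition(dm, 3.5)
            if unique:
                assert got == want


class TestNaming:
    def _families(self, spec):
        # spec: list of (fid, presence dict of copies, peaks dict)
        fams = [Family(family_id=fid, subfamily_ids=[fid]) for fid, _, _ in spec]
        presence = {fid: pres for fid, pres, _ in spec}
        peaks = {fid: pk for fid, _, pk in spec}
        roles = {"spA": "A", "spB": "B", "spO": "outgroup"}
        return name_families(fams, presence, peaks, roles, presence_min_copies=10)

    def test_b_only_families_numbered_by_age(self):
        spec = [
            (f"f{i}", {"spB": 500, "spA": 0}, {"spB": peak})
            for i, peak in enumerate([7.0, 3.0, 5.0, 4.0, 6.0])
        ]
        named = self._families(spec)
        by_name = {f.name: f.peak_divergence["spB"] for f in named}
        assert set(by_name) == {"S1", "S2", "S3", "S4", "S5"}
        assert by_name["S1"] == 3.0 and by_name["S5"] == 7.0  # 1 = youngest

    def test_classes_assigned_by_presence(self):
        spec = [
            ("f1", {"spA": 100, "spB": 100, "spO": 0}, {"spA": 9.0, "spB": 9.0}),
            ("f2", {"spA": 100, "spB": 100, "spO": 50}, {"spA": 14.0, "spB": 14.0, "spO": 14.0}),
            ("f3", {"spA": 100, "spB": 0, "spO": 0}, {"spA": 5.0}),
            ("f4", {"spA": 2, "spB": 300, "spO": 0}, {"spB": 4.0}),
        ]
        named = {f.family_id: f for f in self._families(spec)}
        assert named["f1"].name == "OS1"
        assert named["f2"].name == "OSP1"
        assert named["f4"].name == "S1"  # 2 copies in A are below the presence floor
        assert named["f3"].unclassified  # A-only has no class; flagged, not dropped

    def test_naming_invariant_under_input_order(self):
        spec = [
            (f"f{i}", {"spB": 500}, {"spB": float(p)}) for i, p in enumerate([8, 2, 5])
        ]
        a = {f.family_id: f.name for f in self._families(spec)}
        b = {f.family_id: f.name for f in self._families(spec[::-1])}
        assert a == b


class TestFamilyTree:
    def test_between_family_distance_is_average_pairwise(self):
        subs = [_sub("a1", "A" * 100), _sub("a2", "C" * 2 + "A" * 98), _sub("b1", "C" * 10 + "A" * 90)]
        dm = pairwise_distances(subs)
        fams = [
            Family(family_id="f1", subfamily_ids=["a1", "a2"], name="f1"),
            Family(family_id="f2", subfamily_ids=["b1"], name="f2"),
        ]
        fdm = family_distance_matrix(fams, dm)
        want = np.mean([dm.value("a1", "b1"), dm.value("a2", "b1")])
        assert fdm.value("f1", "f2") == pytest.approx(want)

    def test_leaf_set_matches_family_names(self):
        rng = np.random.default_rng(44)
        subs = [_sub(f"s{i}", "".join(rng.choice(list("ACGT"), 80))) for i in range(4)]
        dm = pairwise_distances(subs)
        fams = [
            Family(family_id=f"f{i}", subfamily_ids=[f"s{i}"], name=f"N{i}") for i in range(4)
        ]
        nwk = family_tree(fams, dm)
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        assert leaves == {"N0", "N1", "N2", "N3"}
        for e in tree.edges():
            if e.length is not None:
                assert e.length >= 0

    def test_two_families_star_tree(self):
        subs = [_sub("a", "A" * 50), _sub("b", "C" * 50)]
        dm = pairwise_distances(subs)
        fams = [Family(family_id="f1", subfamily_ids=["a"], name="f1"),
                Family(family_id="f2", subfamily_ids=["b"], name="f2")]
        nwk = family_tree(fams, dm)
        assert "f1" in nwk and "f2" in nwk and nwk.endswith(";")


def test_family_consensus_majority_with_tie_order():
    subs = [_sub("a", "AAAA"), _sub("b", "CCAA"), _sub("c", "CAAA")]
    # col1: A,C,C -> C; col2: A,C,A -> A; ties break toward A<C<G<T
    assert family_consensus(subs, ["a", "b", "c"]) == "CAAA"
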