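"""Family-level clustering, naming and the distance-based family tree.

Subfamilies are grouped into families by complete-linkage agglomerative
clustering on CpG-masked p-distances between their (core-trimmed, frame-
anchored) consensi, cut so that no within-family pairwise distance exceeds
the element's threshold (3.5% for LINEs, 4.4% for the CpG-rich SINEs, both
configurable).  Families are named by their species-sharing class -- S for
species-B-specific, OS for shared by A and B, OSP for shared with the
outgroup -- and numbered within a class by ascending mean peak divergence,
1 being the youngest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj

from .cosegcore import Subfamily
from .seqio import CpGMask, encode, decode

GAP_CODE = 4


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric percent distances, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


@dataclass
class Family:
    family_id: str
    subfamily_ids: list[str]
    name: str = ""  # {S|OS|OSP}{k} once named
    species_presence: frozenset[str] = frozenset()
    consensus: str = ""
    element: str = ""
    peak_divergence: dict[str, float] = field(default_factory=dict)
    copies_per_3gbp: dict[str, float] = field(default_factory=dict)
    unclassified: bool = False


def pairwise_distances(subfamilies: list[Subfamily]) -> DistanceMatrix:
    """CpG-masked p-distances between frame-anchored, core-trimmed consensi.

    All consensi must share the trimmed core frame.  For each pair, columns
    masked as CpG in *either* consensus are excluded; distance = percent
    mismatches over the shared unmasked columns.
    """
    if not subfamilies:
        raise ValueError("no subfamilies")
    starts = {s.core_start for s in subfamilies}
    lengths = {len(s.consensus) for s in subfamilies}
    if len(starts) != 1 or len(lengths) != 1:
        raise ValueError("consensi do not share the trimmed core coordinate frame")
    L = lengths.pop()
    codes = np.stack([encode(s.consensus) for s in subfamilies])
    masks = np.stack(
        [
            s.cpg.as_bool(L) if s.cpg is not None else np.zeros(L, dtype=bool)
            for s in subfamilies
        ]
    )
    n = len(subfamilies)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(masks[i] | masks[j])
            m = int(keep.sum())
            if m == 0:
                raise ValueError("no shared unmasked columns between consensi")
            d[i, j] = d[j, i] = 100.0 * int((codes[i][keep] != codes[j][keep]).sum()) / m
    return DistanceMatrix(labels=[s.subfamily_id for s in subfamilies], matrix=d)


def _min_partition_bb(valid: np.ndarray, upper: int) -> list[list[int]] | None:
    """Deterministic branch-and-bound minimum partition into threshold-cliques.

    Items are assigned in index order to the first compatible blocks (DFS),
    pruning branches that cannot beat the current best; returns the first
    minimum-size partition found (a canonical choice), or None if no
    partition with fewer than ``upper`` blocks exists.
    """
    n = valid.shape[0]
    best: list[list[int]] | None = None
    best_k = upper

    def dfs(i: int, blocks: list[list[int]]) -> None:
        nonlocal best, best_k
        if len(blocks) >= best_k:
            return
        if i == n:
            best = [list(b) for b in blocks]
            best_k = len(blocks)
            return
        for b in blocks:
            if all(valid[i, j] for j in b):
                b.append(i)
                dfs(i + 1, blocks)
                b.pop()
        blocks.append([i])
        dfs(i + 1, blocks)
        blocks.pop()

    dfs(0, [])
    return best


def cluster_families(dm: DistanceMatrix, threshold: float, exact_limit: int = 16) -> list[Family]:
    """Fewest families such that every within-family distance <= threshold.

    Complete-linkage agglomerative clustering (closest pair merged first) cut
    at the threshold provides the partition; because the greedy merge order
    can occasionally strand a subfamily in its own family, a deterministic
    exact search replaces the complete-linkage result whenever (for inputs up
    to ``exact_limit`` subfamilies) a partition with fewer families exists --
    families should cluster related subfamilies without inflating the family
    count.  The partition is exhaustive and disjoint; threshold 0 puts every
    subfamily (with a distinct consensus) in its own family.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(dm.labels)
    if n == 1:
        groups = [[dm.labels[0]]]
    else:
        Z = sch.linkage(squareform(dm.matrix, checks=False), method="complete")
        flat = sch.fcluster(Z, t=threshold, criterion="distance")
        groups_d: dict[int, list[str]] = {}
        for lab, g in zip(dm.labels, flat):
            groups_d.setdefault(int(g), []).append(lab)
        groups = [sorted(v) for v in groups_d.values()]
        if n <= exact_limit:
            refined = _min_partition_bb(dm.matrix <= threshold, upper=len(groups))
            if refined is not None:
                groups = [sorted(dm.labels[i] for i in block) for block in refined]
    groups.sort(key=lambda g: g[0])
    return [Family(family_id=f"fam{i:02d}", subfamily_ids=g) for i, g in enumerate(groups, 1)]


def family_consensus(subfamilies: list[Subfamily], member_ids: list[str]) -> str:
    """Column-majority consensus over member subfamily consensi (ties A<C<G<T)."""
    members = [s for s in subfamilies if s.subfamily_id in member_ids]
    codes = np.stack([encode(s.consensus) for s in members])
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    return decode(counts.argmax(axis=0).astype(np.uint8))


def name_families(
    families: list[Family],
    presence_by_species: dict[str, dict[str, float]],
    peaks_by_species: dict[str, dict[str, float]],
    species_roles: dict[str, str],
    presence_min_copies: float = 10.0,
) -> list[Family]:
    """Assign S / OS / OSP names by species sharing and relative age.

    ``presence_by_species[family_id][species]`` gives assigned copy counts
    (raw counts, not normalized: a single anomalous read must not create
    presence); a species counts as present at >= ``presence_min_copies``.
    ``species_roles`` maps species label -> {"A", "B", "outgroup"}.  Within a
    class, families are numbered 1..k by ascending mean peak divergence
    (youngest = 1).  A family present only in species A has no class in the
    naming scheme and is flagged unclassified rather than dropped.
    """
    roles = {r: sp for sp, r in species_roles.items()}
    a_sp, b_sp = roles.get("A"), roles.get("B")
    out_sp = roles.get("outgroup")
    classed: dict[str, list[Family]] = {"S": [], "OS": [], "OSP": []}
    for fam in families:
        pres = frozenset(
            sp
            for sp, copies in presence_by_species.get(fam.family_id, {}).items()
            if copies >= presence_min_copies
        )
        fam.species_presence = pres
        fam.peak_divergence = dict(peaks_by_species.get(fam.family_id, {}))
        has_a, has_b = a_sp in pres, b_sp in pres
        has_out = out_sp in pres if out_sp else False
        if has_a and has_b and has_out:
            classed["OSP"].append(fam)
        elif has_a and has_b:
            classed["OS"].append(fam)
        elif has_b and not has_a:
            classed["S"].append(fam)
        else:
            fam.unclassified = True
            fam.name = f"unclassified({fam.family_id})"
    for cls, fams in classed.items():
        def mean_peak(f: Family) -> float:
            vals = [v for v in f.peak_divergence.values() if not np.isnan(v)]
            return float(np.mean(vals)) if vals else np.inf

        for k, fam in enumerate(sorted(fams, key=lambda f: (mean_peak(f), f.family_id)), 1):
            fam.name = f"{cls}{k}"
    return families


def family_distance_matrix(families: list[Family], dm: DistanceMatrix) -> DistanceMatrix:
    """Between-family distance = average pairwise distance of the member
    subfamily consensi of the two families."""
    n = len(families)
    d = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(dm.labels)}
    for i in range(n):
        for j in range(i + 1, n):
            vals = [
                dm.matrix[idx[a], idx[b]]
                for a in families[i].subfamily_ids
                for b in families[j].subfamily_ids
            ]
            d[i, j] = d[j, i] = float(np.mean(vals))
    labels = [f.name or f.family_id for f in families]
    return DistanceMatrix(labels=labels, matrix=d)


def family_tree(families: list[Family], dm: DistanceMatrix) -> str:
    """Neighbor-joining tree (newick) on the between-family average distances.

    Negative branch lengths are clamped to zero.  With fewer than 3 families
    a star tree is returned.
    """
    fdm = family_distance_matrix(families, dm)
    if len(families) < 3:
        leaves = ",".join(f"{lab}:0.0" for lab in fdm.labels)
        return f"({leaves});"
    tree = nj(SkbioDM(fdm.matrix, ids=fdm.labels), neg_as_zero=True)
    return str(tree).strip()


def brute_force_min_partition(
    dm: DistanceMatrix, threshold: float
) -> tuple[list[list[str]] | None, bool]:
    """Exhaustive search for a minimum-family partition under the threshold.

    Returns (one optimal partition as sorted label groups, unique flag).
    Intended as an independent oracle for small n (set partitions grow as the
    Bell numbers).
    """
    labels = dm.labels
    n = len(labels)
    valid = dm.matrix <= threshold

    best: list[list[int]] | None = None
    count_best = 0

    def partitions(seq: list[int]):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [[first] + block] + part[i + 1 :]
            yield [[first]] + part

    for part in partitions(list(range(n))):
        if all(valid[i, j] for block in part for i in block for j in block):
            if best is None or len(part) < len(best):
                best = part
                count_best = 1
            elif len(part) == len(best):
                canon = {frozenset(b) for b in part}
                if canon != {frozenset(b) for b in best}:
                    count_best += 1
    if best is None:
        return None, False
    groups = sorted([sorted(labels[i] for i in block) for block in best])
    return groups, count_best == 1
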