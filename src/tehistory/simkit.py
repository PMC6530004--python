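"""Synthetic read sets with known retrotransposition histories.

The simulator follows the master-lineage model of LINE/SINE evolution: within
each element, retrotransposition happens in bursts, each driven by a single
master sequence; successive masters drift apart by a configurable expected
percent divergence.  Copies planted by a burst of age *a* are the burst master
evolved so that each non-CpG site mutates with probability a/100 (and each CpG
dinucleotide position with probability min(1, kappa*a/100)); copies of
pre-split (ancestral) bursts share the pre-split portion of that evolution and
then evolve independently in each descendant species.  Copies may be
5'-truncated, are planted on a random strand, and are embedded in i.i.d.
random background sequence that is non-homologous between species, then cut
into merged-read-sized fragments.

Substitutions are per-site independent with a uniformly chosen alternative
base; there are no indels, so divergence arithmetic is exactly testable.
Every planted copy is recorded in a truth table with its realized divergence
from its burst master (measured over the master's non-CpG sites, the same
quantity the analysis pipeline estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import ReadSet, encode, decode, revcomp, write_fasta

LINEAGES = ("ancestral", "split_A", "split_B", "outgroup_shared")
SPECIES_A = "species_A"
SPECIES_B = "species_B"
OUTGROUP = "outgroup"

TRUTH_COLUMNS = [
    "copy_id",
    "species",
    "burst_id",
    "true_divergence_realized",
    "copy_start",
    "copy_end",
    "truncated",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ElementModel:
    """A retrotransposon element type and its compositional biases.

    ``cpg_enrichment`` multiplies the probability of drawing G after a C when
    the ancestral master is generated, planting CpG dinucleotides;
    ``cpg_rate_multiplier`` (kappa) accelerates substitution at CpG sites of
    the master during copy evolution.  ``polya_tail`` appends an A-run to the
    element's 3' end (LINEs end in a poly-A; the reconstruction walk uses it
    as a stop signal).
    """

    name: str
    length: int
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cpg_enrichment: float = 1.0
    cpg_rate_multiplier: float = 1.0
    truncation_prob: float = 0.0
    truncation_min_frac: float = 0.5
    polya_tail: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ConfigurationError(f"{self.name}: base composition must sum to 1")
        if self.length < 50:
            raise ConfigurationError(f"{self.name}: element length must be >= 50")
        if not (0 < self.truncation_min_frac <= 1):
            raise ConfigurationError(f"{self.name}: truncation_min_frac must be in (0,1]")
        if self.cpg_enrichment < 0 or self.cpg_rate_multiplier < 1:
            raise ConfigurationError(f"{self.name}: invalid CpG parameters")

    @property
    def total_length(self) -> int:
        return self.length + self.polya_tail


@dataclass(frozen=True)
class BurstSpec:
    """One retrotransposition burst of one element.

    ``age_divergence`` is the expected percent divergence (per non-CpG site)
    of the burst's copies today -- the molecular-clock proxy for its age.
    ``master_drift`` is the expected percent divergence of this burst's master
    from the previous (older) burst's master in the element's master chain.
    """

    burst_id: str
    element: str
    lineage: str
    age_divergence: float
    copy_count: int
    master_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ConfigurationError(f"{self.burst_id}: unknown lineage {self.lineage!r}")
        if self.age_divergence < 0:
            raise ConfigurationError(f"{self.burst_id}: negative age_divergence")
        if self.copy_count <= 0:
            raise ConfigurationError(f"{self.burst_id}: copy_count must be positive")
        if self.master_drift < 0:
            raise ConfigurationError(f"{self.burst_id}: negative master_drift")


@dataclass(frozen=True)
class SimulationConfig:
    elements: tuple[ElementModel, ...]
    bursts: tuple[BurstSpec, ...]
    split_divergence: float = 8.5
    outgroup_split_divergence: float | None = None
    background_genome_bp: int = 1_000_000
    read_length_range: tuple[int, int] = (450, 550)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.read_length_range
        if not (100 <= lo <= hi <= 5000):
            raise ConfigurationError("read_length_range must lie within [100, 5000]")
        names = {e.name for e in self.elements}
        if len(names) != len(self.elements):
            raise ConfigurationError("duplicate element names")
        by_elem: dict[str, list[BurstSpec]] = {}
        for b in self.bursts:
            if b.element not in names:
                raise ConfigurationError(f"burst {b.burst_id}: unknown element {b.element!r}")
            by_elem.setdefault(b.element, []).append(b)
        for elem, bl in by_elem.items():
            ages = [b.age_divergence for b in bl]
            if any(a2 >= a1 for a1, a2 in zip(ages, ages[1:])):
                raise ConfigurationError(f"{elem}: bursts must be listed in strictly decreasing age order")
            for b in bl:
                if b.lineage in ("ancestral", "outgroup_shared") and b.age_divergence < self.split_divergence:
                    raise ConfigurationError(
                        f"burst {b.burst_id}: ancestral burst younger than split divergence"
                    )
                if b.lineage == "outgroup_shared":
                    if self.outgroup_split_divergence is None:
                        raise ConfigurationError(
                            f"burst {b.burst_id}: outgroup_shared burst requires outgroup_split_divergence"
                        )
                    if self.outgroup_split_divergence < self.split_divergence:
                        raise ConfigurationError(
                            "outgroup_split_divergence must be >= split_divergence"
                        )
                    if b.age_divergence < self.outgroup_split_divergence:
                        raise ConfigurationError(
                            f"burst {b.burst_id}: outgroup_shared burst younger than outgroup split"
                        )
        # element copies must fit the per-species background budget
        elem_by_name = {e.name: e for e in self.elements}
        for sp in self.species:
            bp = sum(
                elem_by_name[b.element].total_length * b.copy_count
                for b in self.bursts
                if sp in _burst_species(b)
            )
            if bp > self.background_genome_bp:
                raise ConfigurationError(
                    f"{sp}: element copies ({bp} bp) exceed background budget "
                    f"({self.background_genome_bp} bp)"
                )

    @property
    def species(self) -> tuple[str, ...]:
        has_outgroup = any(b.lineage == "outgroup_shared" for b in self.bursts)
        return (SPECIES_A, SPECIES_B, OUTGROUP) if has_outgroup else (SPECIES_A, SPECIES_B)


def _burst_species(b: BurstSpec) -> tuple[str, ...]:
    return {
        "ancestral": (SPECIES_A, SPECIES_B),
        "split_A": (SPECIES_A,),
        "split_B": (SPECIES_B,),
        "outgroup_shared": (SPECIES_A, SPECIES_B, OUTGROUP),
    }[b.lineage]


# ---------------------------------------------------------------------------
# sequence evolution


def _cpg_site_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask over positions that belong to a CG dinucleotide."""
    mask = np.zeros(len(codes), dtype=bool)
    if len(codes) >= 2:
        is_cg = (codes[:-1] == 1) & (codes[1:] == 2)
        mask[:-1] |= is_cg
        mask[1:] |= is_cg
    return mask


def _mutate(codes: np.ndarray, p_site: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mutate each site with its probability; target uniform among the 3 others."""
    hit = rng.random(len(codes)) < p_site
    out = codes.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def evolve_master(
    parent: str | np.ndarray,
    drift_pct: float,
    element: ElementModel,
    rng: np.random.Generator,
) -> str | np.ndarray:
    """Evolve a master sequence by an expected percent divergence.

    Each non-CpG site mutates with probability drift_pct/100, each position of
    a CpG dinucleotide (defined on ``parent``) with probability
    min(1, kappa * drift_pct/100).  Length is preserved (no indels).
    """
    if drift_pct < 0:
        raise ConfigurationError("drift_pct must be >= 0")
    as_str = isinstance(parent, str)
    codes = encode(parent) if as_str else parent
    if len(codes) == 0:
        raise ConfigurationError("empty parent sequence")
    p = np.full(len(codes), drift_pct / 100.0)
    cpg = _cpg_site_mask(codes)
    p[cpg] = min(1.0, element.cpg_rate_multiplier * drift_pct / 100.0)
    child = _mutate(codes, p, rng)
    return decode(child) if as_str else child


def _random_master(element: ElementModel, rng: np.random.Generator) -> np.ndarray:
    """Ancestral master: first-order chain boosting G after C by cpg_enrichment."""
    comp = np.asarray(element.base_composition)
    seq = np.empty(element.length, dtype=np.uint8)
    seq[0] = rng.choice(4, p=comp)
    boosted = comp.copy()
    boosted[2] *= element.cpg_enrichment
    boosted /= boosted.sum()
    for i in range(1, element.length):
        p = boosted if seq[i - 1] == 1 else comp
        seq[i] = rng.choice(4, p=p)
    if element.polya_tail:
        seq = np.concatenate([seq, np.zeros(element.polya_tail, dtype=np.uint8)])
    return seq


# ---------------------------------------------------------------------------
# simulation


def _evolve_copy_stages(
    master: np.ndarray,
    stages: list[float],
    element: ElementModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a copy through successive divergence stages (CpG set fixed on master)."""
    cpg = _cpg_site_mask(master)
    out = master
    for pct in stages:
        p = np.full(len(master), pct / 100.0)
        p[cpg] = min(1.0, element.cpg_rate_multiplier * pct / 100.0)
        out = _mutate(out, p, rng)
    return out


def _realized_divergence(copy: np.ndarray, master: np.ndarray, start: int, end: int) -> float:
    """Percent mismatch vs master over the master's non-CpG sites in [start, end] (1-based)."""
    cpg = _cpg_site_mask(master)
    sl = slice(start - 1, end)
    keep = ~cpg[sl]
    n = int(keep.sum())
    if n == 0:
        return 0.0
    mism = int((copy[sl][keep] != master[sl][keep]).sum())
    return 100.0 * mism / n


def simulate(
    config: SimulationConfig,
) -> tuple[dict[str, ReadSet], pd.DataFrame, dict[str, str]]:
    """Run the burst model; returns (per-species ReadSet, TruthTable, burst masters).

    Deterministic given ``config.seed``.  Ancestral bursts appear in both
    split species with the pre-split portion of copy evolution shared and the
    post-split portion independent per species.
    """
    rng = np.random.default_rng(config.seed)
    elem_by_name = {e.name: e for e in config.elements}
    species = config.species
    s = config.split_divergence
    og = config.outgroup_split_divergence

    masters: dict[str, np.ndarray] = {}
    copies: dict[str, list[tuple[str, str, np.ndarray, int, int, bool]]] = {sp: [] for sp in species}
    truth_rows: list[dict] = []

    for element in config.elements:
        chain: np.ndarray | None = None
        bursts = [b for b in config.bursts if b.element == element.name]
        for b in bursts:
            if chain is None:
                chain = _random_master(element, rng)
            else:
                chain = evolve_master(chain, b.master_drift, element, rng)
            masters[b.burst_id] = chain
            master = chain
            total_len = len(master)
            for ci in range(b.copy_count):
                a = b.age_divergence
                if b.lineage == "split_A":
                    staged = {SPECIES_A: [a]}
                elif b.lineage == "split_B":
                    staged = {SPECIES_B: [a]}
                elif b.lineage == "ancestral":
                    shared = _evolve_copy_stages(master, [a - s], element, rng)
                    staged = {SPECIES_A: shared, SPECIES_B: shared, "_post": s}
                else:  # outgroup_shared
                    pre_og = _evolve_copy_stages(master, [a - og], element, rng)
                    og_copy = _evolve_copy_stages(pre_og, [og], element, rng)
                    mid = _evolve_copy_stages(pre_og, [og - s], element, rng)
                    staged = {
                        SPECIES_A: mid,
                        SPECIES_B: mid,
                        OUTGROUP: og_copy,
                        "_post": s,
                        "_og_done": True,
                    }
                # truncation and strand are per copy per species (independent
                # insertion events happen once, pre-split, for shared bursts:
                # the *same* retained interval and strand in both species)
                if rng.random() < element.truncation_prob:
                    frac = rng.uniform(element.truncation_min_frac, 1.0)
                    start = total_len - max(1, int(round(frac * total_len))) + 1
                    truncated = True
                else:
                    start = 1
                    truncated = False
                end = total_len
                strand = "+" if rng.random() < 0.5 else "-"
                copy_id = f"{b.burst_id}_c{ci:05d}"
                for sp in _burst_species(b):
                    if isinstance(staged.get(sp), list):
                        final = _evolve_copy_stages(master, staged[sp], element, rng)
                    elif "_og_done" in staged and sp == OUTGROUP:
                        final = staged[OUTGROUP]
                    else:
                        final = _evolve_copy_stages(staged[sp], [staged["_post"]], element, rng)
                    div = _realized_divergence(final, master, start, end)
                    seq = final[start - 1 : end]
                    truth_rows.append(
                        dict(
                            copy_id=copy_id,
                            species=sp,
                            burst_id=b.burst_id,
                            true_divergence_realized=round(div, 6),
                            copy_start=start,
                            copy_end=end,
                            truncated=truncated,
                        )
                    )
                    copies[sp].append((copy_id, b.burst_id, seq, start, end, strand == "-"))

    # reads
    readsets: dict[str, ReadSet] = {}
    lo, hi = config.read_length_range
    for sp in species:
        reads: list[tuple[str, str]] = []
        # element-copy reads: each copy embedded in random flanks and tiled
        for copy_id, burst_id, seq, start, end, minus in copies[sp]:
            s_str = decode(seq)
            if minus:
                s_str = revcomp(s_str)
            pos = 0
            ri = 0
            n = len(s_str)
            while pos < n:
                rlen = int(rng.integers(lo, hi + 1))
                chunk = s_str[pos : pos + rlen]
                pad = rlen - len(chunk)
                left = int(rng.integers(0, pad + 1)) if pad else 0
                right = pad - left
                flank_l = decode(rng.integers(0, 4, size=left).astype(np.uint8)) if left else ""
                flank_r = decode(rng.integers(0, 4, size=right).astype(np.uint8)) if right else ""
                reads.append((f"{sp}_{copy_id}_r{ri}", flank_l + chunk + flank_r))
                pos += rlen
                ri += 1
        # background reads: i.i.d. random genome fragmented to the read range
        remaining = config.background_genome_bp
        bi = 0
        while remaining > 0:
            rlen = min(int(rng.integers(lo, hi + 1)), remaining)
            reads.append((f"{sp}_bg{bi:07d}", decode(rng.integers(0, 4, size=rlen).astype(np.uint8))))
            remaining -= rlen
            bi += 1
        readsets[sp] = ReadSet(species=sp, reads=reads)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    master_strs = {bid: decode(m) for bid, m in masters.items()}
    return readsets, truth, master_strs


def write_outputs(
    outdir: str | Path,
    readsets: dict[str, ReadSet],
    truth: pd.DataFrame,
    masters: dict[str, str],
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, rs in readsets.items():
        write_fasta(rs, outdir / f"reads_{sp}.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_fasta(list(masters.items()), outdir / "masters.fasta")


# ---------------------------------------------------------------------------
# canned scenario


LINE = "LINE"
SINE = "SINE"


def study_scenario(
    background_genome_bp: int = 20_000_000, seed: int = 17, copy_scale: float = 1.0
) -> SimulationConfig:
    """Two-species history with the qualitative structure of the study system.

    Species A stands for the lineage that lost LINE activity after the split
    (the *Oryzomys* analog), species B for the basal lineage where LINE
    activity rebounded (*Sigmodon* analog).  Three shared LINE bursts of
    decreasing age precede the split; the youngest shared LINE family keeps
    amplifying briefly after the split in species A only (a split_A companion
    burst), yielding ~1.5x more copies of that family in A.  Five LINE bursts
    are specific to species B and younger than the split.  One large SINE
    burst is shared, coincident in age with the second-youngest shared LINE
    burst, and no SINE burst is younger than the split -- so the SINE dies in
    both species while the LINE dies only in A.

    Copy counts are desk-scale and illustrative; ``copy_scale`` shrinks or
    grows them together.
    """

    def n(x: int) -> int:
        return max(1, int(round(x * copy_scale)))

    line = ElementModel(
        name=LINE,
        length=360,
        base_composition=(0.40, 0.18, 0.18, 0.24),
        cpg_enrichment=1.0,
        cpg_rate_multiplier=3.0,
        truncation_prob=0.25,
        truncation_min_frac=0.5,
        polya_tail=14,
    )
    sine = ElementModel(
        name=SINE,
        length=150,
        base_composition=(0.22, 0.30, 0.26, 0.22),
        cpg_enrichment=3.0,
        cpg_rate_multiplier=3.0,
        truncation_prob=0.0,
    )
    bursts = (
        BurstSpec("L_anc3", LINE, "ancestral", 16.0, n(600), 0.0),
        BurstSpec("L_anc2", LINE, "ancestral", 12.0, n(600), 8.0),
        BurstSpec("L_anc1", LINE, "ancestral", 9.0, n(600), 8.0),
        BurstSpec("L_tailA", LINE, "split_A", 8.2, n(300), 1.0),
        BurstSpec("L_b1", LINE, "split_B", 7.0, n(600), 7.0),
        BurstSpec("L_b2", LINE, "split_B", 6.0, n(600), 7.0),
        BurstSpec("L_b3", LINE, "split_B", 5.0, n(600), 7.0),
        BurstSpec("L_b4", LINE, "split_B", 4.0, n(600), 7.0),
        BurstSpec("L_b5", LINE, "split_B", 3.0, n(600), 7.0),
        BurstSpec("S_anc1", SINE, "ancestral", 12.0, n(3000), 0.0),
    )
    return SimulationConfig(
        elements=(line, sine),
        bursts=bursts,
        split_divergence=8.5,
        background_genome_bp=background_genome_bp,
        read_length_range=(450, 550),
        seed=seed,
    )
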