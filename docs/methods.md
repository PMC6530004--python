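# Methods

## The burst model behind the simulator

`simkit` generates read sets under an explicit master-lineage model. Each
element (a LINE-like long, A-rich element; a SINE-like short, CpG-rich
element) carries a chain of burst masters: the master of burst *i*+1 is the
master of burst *i* mutated at an expected `master_drift` percent of sites.
The chain follows the listed (strictly age-decreasing) burst order regardless
of lineage labels — a sequence-generation device, not a claim that, say, a
species-B master literally descends from a species-A one; only the pairwise
distances between masters matter downstream.

A burst of age *a* (expected percent divergence of its copies today) plants
`copy_count` copies, each the master with every non-CpG site mutated
independently with probability *a*/100 and every CpG-dinucleotide position
with probability min(1, κ·*a*/100); substitution targets are uniform over the
three alternatives, and there are no indels, so divergence arithmetic is
exactly checkable against binomial expectations. For bursts older than the
species split (lineage `ancestral`/`outgroup_shared`), the copy evolves
*a* − *s* first (the shared, pre-split history: same retained interval and
strand in both species), then *s* independently per descendant species.
Because substitutions can coincide across stages, multi-stage copies realize
slightly less than *a* (e.g. ≈ 9.7% for *a* = 10, *s* = 5); the truth table
records the realized divergence of every copy, measured over the master's
non-CpG sites — the same quantity the pipeline estimates.

Copies may be 5′-truncated (uniform retained 3′ fraction in
[`truncation_min_frac`, 1]), are planted on a random strand, embedded in
i.i.d. random background sequence (non-homologous between species, so
background reads cannot pass the 90% coverage filter by chance at these
scales), and cut into merged-read-sized fragments (default 450–550 bp).
Reads are error-free; sequencing error is treated as absorbed into copy
divergence. Deliberately not modeled: indels, recombination between
elements, paired-end structure, quality values, genome-size differences
between species. Passing tests therefore demonstrate recovery of
substitution-clock structure, not robustness to indel-rich or low-complexity
real data.

### The canned scenario

`study_scenario()` encodes the study design the package exists for: three
shared LINE bursts (ages 16/12/9%, 600 copies each) before a split at 8.5%
divergence; a small post-split continuation of the youngest shared LINE
lineage in species A only (300 copies at 8.2%, master 1% from its parent),
which clusters into the same family and yields the ~1.5× copy asymmetry; five
species-B-only LINE bursts (ages 7–3%, 600 copies each); and one large shared
SINE burst (3000 copies/species) at age 12%, coincident with the
second-youngest shared LINE burst and with nothing younger — so the SINE is
called extinct in both species and the LINE only in species A. Master drift
between family-level bursts is 7–8% so that realized inter-master distances
stay safely above the 3.5% family threshold (binomial sd ≈ 1.1 pt at 360 bp).
The LINE model is 360 bp — standing for the 3′ ORF2 region that this kind of
classification actually uses, and short enough that a merged read can cover
>90% of it — with a 14 bp poly-A tail (the walk's natural 3′ stop signal);
the SINE is 150 bp with CpG-enriched composition. κ = 3 for both elements.
Copy counts are desk-scale and illustrative; `copy_scale` shrinks or grows
them together with the subfamily floors left to the caller.

## Alignment engine

Searches use a numba-compiled affine-gap Smith–Waterman (match +2, mismatch
−3, gap open −5, gap extend −2; a length-L gap costs open + (L−1)·extend; all
scores config-exposed). `N` never matches. Reads are prefiltered by exact
k-mer sharing with the library (k = 12, ≥ 3 shared k-mers on the better
strand) — at 12-mer scale a random 500 bp read shares ≈ 0.2 k-mers with a
few-kb library while a 20%-diverged homolog still shares ≳ 10 — so
background reads never reach the aligner.

Local alignment maximizes score and therefore trims mismatch-dense ends,
which makes old copies look systematically younger (we measured ≈ −1.3 pt on
a 12%-diverged CpG-rich element). Retained hits are therefore extended along
their end diagonals to the full read/consensus overlap before coverage,
identity and divergence are computed; after extension, recovered peaks match
the truth-table divergences to ≈ 0.1 pt. Per-hit divergence excludes
consensus CpG columns and gap columns from both numerator and denominator.

## Co-segregation partitioning

The subfamily partitioner works on an anchored alignment (reads projected
onto consensus columns; read insertions dropped). A candidate diagnostic
variant is a (column, base) pair differing from the current partition's
majority consensus, outside consensus CpG columns, with carrier count ≥ the
subfamily size floor. The split criterion accepts a variant pair when its
joint carrier count is ≥ the floor, leaves a remainder ≥ the floor, and
exceeds `enrichment_factor` × m·m′/N (the independence expectation). The
default factor is 1.5: a balanced two-burst split has enrichment exactly 2
(joint = m = N/2), so any stricter default would be blind to equal bursts,
while independent noise pairs are excluded by the size floor alone (their
joints are ≈ m·m′/N ≪ 250 at realistic depths). The carriers of the
highest-joint qualifying pair (ties: lowest column/base indices) are split
off, both sides are re-polished by nearest-consensus reassignment (mismatch
count over non-gap, non-CpG columns; ties to the earlier-created side) until
stable, and the procedure recurses. All tie-breaks are total, so the
partition is deterministic.

The two-round protocol runs round 1 per species against the walked seed
consensus and round 2 on both species pooled against all round-1 consensi —
old subfamilies that are unreachable from the young seed (>~25% divergence)
are reached by laddering through intermediate round-1 consensi. Round-2
consensi are trimmed to the column interval covered by every subfamily and
CpG-masked; subfamilies that receive no assignments in the final search are
dropped.

## Families, tree, landscapes

Subfamily p-distances are computed over shared unmasked core columns.
Families are the fewest groups in which every within-family pairwise distance
is ≤ the threshold (3.5% LINE / 4.4% SINE): complete-linkage clustering cut
at the threshold supplies the partition, and — because greedy merge order can
occasionally strand a middle subfamily in a singleton family — a
deterministic branch-and-bound search (inputs ≤ 16 subfamilies) replaces it
whenever a smaller partition exists. Family presence in a species requires
≥ 10 raw assigned copies (a normalized floor would let a single anomalous
read grant presence at small library sizes); naming is S (B-only), OS (A+B),
OSP (A+B+outgroup), numbered by ascending mean peak; A-only families have no
class in this scheme and are flagged unclassified rather than dropped. The
family tree is neighbor-joining on average between-family subfamily
distances, negative branch lengths clamped to zero.

Divergence landscapes use 1% histogram bins and a Gaussian kernel of σ = 0.4
percentage points evaluated on a 0.01-pt grid over [0, 50]; the peak is the
grid argmax (ties toward lower divergence). Copy numbers are normalized as
raw × 3×10⁹ / total searched bp. Note the peak estimator's intrinsic noise:
per-copy divergence is Binomial(L', a/100)/L' over L' unmasked columns, so at
L' ≈ 300 the argmax has sd ≈ 0.36 pt at n = 500 regardless of implementation;
peak-recovery checks at the ±0.5 pt level therefore use a 1 kb element
(sd ≈ 0.1 pt), with reads long enough to span it.

The event report orders families oldest-first by mean peak and derives:
cross-species synchrony (|Δpeak| ≤ 1.0 pt — one histogram bin — within a
family), cross-family coincidence (same tolerance on mean peaks), copy
asymmetry (max/min copies per 3 Gbp ≥ 1.3 between species), post-split
activity (any peak below the split estimate), and extinction per species and
element: extinct when no family present in that species peaks below
split − 2 pt. Extinction is a statement about the *absence* of recent
families and hence bounded by the detection floor (subfamily size minima,
presence floor), which the report records next to the calls. The split
estimate is taken from configuration/simulation truth when known; otherwise
it is derived as the oldest species-specific peak plus one bandwidth and
flagged as derived.

## Determinism and problem sizes

Every stage is a deterministic function of its inputs and the seed; the
pipeline manifest records parameter and output hashes per stage, and
re-running a config byte-reproduces all TSV/JSON outputs. The simulate stage
is cached on disk and re-used when its config hash matches. Default
end-to-end runs use 20 Mbp background per species (~90 k reads total), which
resolves all planted families while keeping a full run in a few minutes on
one CPU; the test suite's miniature pipeline scales copy counts and subfamily
floors down together (×0.12, floors 25–120) to exercise the same code paths
quickly.

## Known limitations

- No indel handling in consensus building or divergence (substitution-only
  model end to end); real L1 alignments contain indels that would perturb
  both the anchored frame and p-distances.
- The walk stops at poly-A, support loss, or a length cap — it cannot
  recognize ORF boundaries, so on real data the reconstructed consensus may
  run past ORF2 into the 3′ UTR.
- Tri-segregating (3-way) diagnostic sites are not modeled; recursion
  achieves multi-way partitions through repeated bipartition.
- Percent divergence is never converted to absolute time; rate variation
  between elements (even CpG-masked) and across history makes a global
  conversion unreliable, and all conclusions are stated on the divergence
  scale.
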