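# Methods notes

## Model and procedure

The package operationalises species delimitation by mutual allelic
exclusivity. For each co-dominant nuclear marker, phased allelic sequences
are collapsed into haplotypes; haplotypes observed together in a heterozygous
individual are linked, and the connected components of this co-occurrence
graph are the marker's allele pools. Every individual's two alleles lie in
one pool, so pools induce a partition of the individuals — the single-locus
fields for recombination (sl-FFRs). Haplotypes carried only by homozygotes
and never co-occurring form singleton pools; two homozygotes for the *same*
haplotype share a pool (they share an allele), whereas two haplotypes joined
only by network edges or median vectors do not (a median vector is a
hypothesis, not an observed allele — a deliberate resolution of a case the
delimitation rule leaves open). Haploid markers are sorted into haplogroups
by exact haplotype identity, with no distance-based merging.

Congruence across M independent datasets is quantified on bipartitions: a
partition with k blocks supports the 2^(k−1)−1 splits of the sample obtained
as unions of its blocks versus the rest. Support = fraction of datasets
supporting the split (exact rationals internally; percentages displayed with
half-up rounding, so 1/3 prints as 33%). Reconciliation keeps rows with
support strictly above the cutoff (default 1/2 — strict, so 1/3 is dropped
while 2/3 survives), verifies pairwise compatibility (some pair of opposite
sides must be disjoint), and intersects the kept splits; incompatible kept
splits are reported as an error listing the pairs, never silently resolved.
The partition join (finest common coarsening, union-find over block
co-membership) reproduces the classic multilocus-FFR rule; the meet
(coarsest common refinement) yields the atomic regions of reconciliation
drawings.

Important caveat inherited from the method: bipartition scoring requires all
markers to be typed over the same individuals (`restrict_to_common` trims to
the shared set when explicitly requested). Input partitions are weighted
equally; non-molecular groupings can be passed as extra partitions, but
their independence is the caller's responsibility.

## Haplotype identity and input conventions

Haplotype equality is exact, case-insensitive string identity with the
alignment gap `-` as a fifth character state and no expansion of IUPAC
ambiguity codes (a warning is logged when codes are present). Curation of
hypervariable regions is an upstream step, exposed only as an optional
1-based column-exclusion list per marker. A diploid individual represented
by a single sequence is accepted as an assumed homozygote and logged loudly.
Haplotype ids (`h1, h2, …`) follow first appearance after sorting records by
sequence id, making all outputs byte-stable. A haplotype's `count` is the
number of input sequence records collapsed into it, while its `members` set
drives the drawing conventions (diameters reflect individuals harbouring the
haplotype).

## Median-joining networks

Pairwise distances are per-column mismatch counts (`fifth_state` default, or
`ignore` to skip gapped columns); all characters are weighted equally. The
ε-relaxed minimum-spanning network keeps an edge iff its length is at most
the bottleneck (minimax-path) distance of its endpoints plus ε; ε = 0 gives
exactly the union of all minimum spanning trees. The median-joining
iteration computes, for every triplet of mutually connected nodes, the
column-wise majority-consensus vector, breaking three-way ties toward the
triplet member with the smallest node id (observed before median, numeric
order within each); candidates are evaluated in lexicographic sequence order
and added greedily whenever they strictly reduce the minimum-spanning-tree
total weight of the node set — the "connection cost" here, a choice the
original algorithm description leaves open. Peripheral medians (degree ≤ 1)
are pruned at the end. An iteration cap of 10 × (number of haplotypes)
guards termination. ε and the triplet/tie conventions are reported because
published figures built with other implementations need not be reproduced
edge-for-edge. Networks serve visualisation and reporting only: FFR
delineation never reads network topology.

## Synthetic data

The generator emulates the regime where pool-based delimitation is
meaningful: reproductively isolated species whose allele pools are mutually
exclusive but not necessarily monophyletic. Each species/marker pool is a
star genealogy — a species ancestor plus `intra_mutations` fresh mutations
per haplotype, positions drawn without replacement within a haplotype (no
back-mutation), so pairwise distances are analysable in closed form. Species
ancestors are mutated from a common root at disjoint position sets
(`inter_mutations` each, so ancestors differ at 2×`inter_mutations`
positions); the config requires 2×`inter_mutations` ≥ 2×`intra_mutations`+1,
which bounds any cross-species haplotype distance away from zero, and pool
disjointness is additionally asserted at generation. Genotypes are two
independent draws (one for haploid markers) from Dirichlet-distributed
haplotype frequencies: concentration 1.0 by default (realistically skewed
pools, like the common-plus-singletons pattern of real surveys).

Defaults: 2 species × 20 individuals, markers `nuc1`/`nuc2` (diploid) and
`mt` (haploid), sequence length 200, 4 haplotypes per pool, 2 intra- and 8
inter-mutations, seed 0. The *sufficient-sampling* preset used by the
recovery checks (20 individuals and 3 haplotypes per pool, concentration
8.0) realises "the pool is well sampled" operationally: every haplotype has
a non-negligible expected count (≈ 13 copies among 40 draws), so
heterozygotes chain each pool into one component and each marker's partition
refines the species truth. The preset was fixed from that expected-count
argument, not fitted to outcomes.

Contamination scenarios (all seeded from the config seed): an F1 hybrid adds
an individual with one allele from each parent pool at every diploid marker
(and the first parent's haplotype at haploid markers — it is booked in that
parent's truth block, the convention for organelle-typed vouchers);
introgression replaces one allele of one individual at one marker with an
other-species haplotype; shared ancestral polymorphism hands one existing
haplotype to an individual of the other species at one marker. One hybrid
collapses the multilocus join to a single block; one introgressed allele in
one of three markers leaves the species split at 2/3 support, still above
the cutoff.

What the simulator does **not** model: within-marker recombination,
selection, coalescent time structure, sequencing or phasing error, missing
data. Passing recovery tests therefore show correctness of the delimitation
logic under clean, well-sampled data, not robustness to those real-data
complications.

## Numerical and rendering choices

Support fractions are exact `Fraction`s; only display rounds. Bipartitions
are canonicalised as the side not containing the smallest individual id, and
block order (decreasing size, then smallest member) makes all reports
deterministic. SVG rendering is a pure function of its inputs and the layout
seed (seeded spring layout, fixed-precision coordinates): identical calls
give byte-identical files. Node diameter — not area — is linear in the count,
following the source figures' convention; an area mode exists for
perceptually linear scaling. Curve width is linear in heterozygote count and
bipartition stroke width in the number of supporting datasets; tests parse
the emitted attributes to assert the linearity.

## Problem sizes

Tests and the acceptance script run on the 74-sample worked example, random
datasets of ≤ 12 individuals against brute-force oracles, median-joining
inputs of ≤ 6 haplotypes × ≤ 8 columns against an exhaustive quasi-median
closure, and 20-seed recovery sweeps at 40 individuals × 3 markers — sizes
at which the independent oracles (spanning-tree enumeration, Floyd–Warshall
minimax, transitive-closure passes) are exact and fast.

## Known limitations

* Bipartition enumeration is exponential in the number of blocks; a cap
  (default 20 blocks) must be raised explicitly for fragmented datasets.
* Haplogroup assignment has no tolerance for sequencing error (one mismatch
  = new haplogroup), matching the method but not always practice.
* The genotype-TSV reader infers a marker as haploid only when *every* row
  leaves `allele_2` empty; an all-homozygous diploid marker typed with
  single entries is indistinguishable from a haploid one.
* Reconciliation reports incompatible above-threshold bipartitions as a
  conflict rather than choosing among them; such conflicts cannot arise in
  the worked example but can in principle.
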