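"""From haplonet to haploweb: allele pools and fields for recombination.

A haploweb is a haplotype network overlaid with weighted links between
haplotypes found co-occurring in heterozygous individuals.  Chains of such
co-occurrence (plus plain allele sharing) define *allele pools*; the groups of
individuals whose alleles fall in the same pool are single-locus fields for
recombination (sl-FFRs): sets of individuals mutually connected by actual or
potential gene flow at that locus.  Individuals in different sl-FFRs share no
allele — the mutual-allelic-exclusivity criterion for species boundaries.

Pools are computed from co-occurrence and allele sharing only, never from
network edges: two haplotypes joined by a mutational path (even through a
median vector) but never seen together in one genome remain in separate
pools.

For non-recombining haploid markers the analogous grouping is the
*haplogroup*: individuals carrying an identical haplotype.  No distance
threshold is applied — haplotypes one mutation apart form distinct
haplogroups.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConsistencyError, FormatError, PloidyError
from .io_model import MarkerDataset
from .netbuild import HaplotypeNetwork


@dataclass(frozen=True)
class CooccurrenceLink:
    """Two haplotypes seen together in `weight` heterozygous individuals."""

    hap_u: str
    hap_v: str
    weight: int

    def __post_init__(self):
        if self.hap_u == self.hap_v:
            raise ConsistencyError("co-occurrence link endpoints must differ")
        if self.weight < 1:
            raise ConsistencyError("co-occurrence link weight must be >= 1")


@dataclass(frozen=True)
class Partition:
    """A named division of the individual set into disjoint blocks.

    Blocks are stored in canonical order: decreasing size, ties broken by the
    smallest member id.
    """

    label: str
    universe: tuple[str, ...]
    blocks: tuple[frozenset[str], ...]

    @staticmethod
    def from_blocks(
        label: str, universe: Sequence[str], blocks: Iterable[Iterable[str]]
    ) -> "Partition":
        bl = [frozenset(b) for b in blocks]
        return Partition(label, tuple(universe), tuple(_canonical_order(bl)))

    def __post_init__(self):
        if not self.blocks:
            raise FormatError(f"partition {self.label!r} has no blocks")
        seen: set[str] = set()
        for b in self.blocks:
            if not b:
                raise FormatError(f"partition {self.label!r} has an empty block")
            if seen & b:
                raise FormatError(f"partition {self.label!r} has overlapping blocks")
            seen |= b
        if seen != set(self.universe):
            raise FormatError(
                f"partition {self.label!r}: blocks do not cover the universe"
            )

    @property
    def k(self) -> int:
        return len(self.blocks)

    def block_of(self, individual: str) -> frozenset[str]:
        for b in self.blocks:
            if individual in b:
                return b
        raise KeyError(individual)

    def block_sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]

    def relabel(self, mapping: dict[str, str], label: str | None = None) -> "Partition":
        return Partition.from_blocks(
            label if label is not None else self.label,
            [mapping[i] for i in self.universe],
            [{mapping[i] for i in b} for b in self.blocks],
        )


def _canonical_order(blocks: list[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(blocks, key=lambda b: (-len(b), min(b)))


def cooccurrence_links(ds: MarkerDataset) -> list[CooccurrenceLink]:
    """One link per unordered heterozygous genotype, weighted by multiplicity."""
    if ds.ploidy != 2:
        raise PloidyError(
            f"marker {ds.marker!r} is haploid; use haplogroups() instead of "
            "co-occurrence links"
        )
    pairs = Counter(
        tuple(sorted(set(ds.genotypes[i])))
        for i in ds.universe
        if ds.is_heterozygote(i)
    )
    links = [CooccurrenceLink(u, v, w) for (u, v), w in pairs.items()]
    links.sort(key=lambda l: (-l.weight, l.hap_u, l.hap_v))
    return links


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self) -> list[frozenset]:
        out: dict = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return [frozenset(s) for s in out.values()]


def allele_pools(ds: MarkerDataset) -> list[frozenset[str]]:
    """Partition the marker's haplotypes into pools of co-occurring alleles.

    Pools are the connected components of the graph on all haplotype ids with
    co-occurrence links as edges; a haplotype only ever seen in homozygotes
    (and never co-occurring) is its own singleton pool.
    """
    if ds.ploidy != 2:
        raise PloidyError(
            f"marker {ds.marker!r} is haploid; allele pools are undefined"
        )
    uf = _UnionFind(ds.all_hap_ids())
    for link in cooccurrence_links(ds):
        uf.union(link.hap_u, link.hap_v)
    return _canonical_order(uf.groups())


def delineate_sl_ffrs(ds: MarkerDataset) -> Partition:
    """Single-locus fields for recombination of a diploid marker.

    Equivalently the connected components of the bipartite individual–
    haplotype sharing graph: both alleles of a heterozygote share a pool by
    construction, so each individual maps to exactly one pool.
    """
    pools = allele_pools(ds)
    pool_of: dict[str, int] = {}
    for i, pool in enumerate(pools):
        for h in pool:
            pool_of[h] = i
    blocks: dict[int, set[str]] = {}
    for ind in ds.universe:
        idx = {pool_of[h] for h in ds.genotypes[ind]}
        assert len(idx) == 1, "alleles of one individual must share a pool"
        blocks.setdefault(idx.pop(), set()).add(ind)
    return Partition.from_blocks(ds.marker, ds.universe, blocks.values())


def haplogroups(ds: MarkerDataset) -> Partition:
    """Group individuals of a haploid marker by identical haplotype."""
    if ds.ploidy != 1:
        raise PloidyError(
            f"marker {ds.marker!r} is diploid; use delineate_sl_ffrs()"
        )
    blocks: dict[str, set[str]] = {}
    for ind in ds.universe:
        (h,) = ds.genotypes[ind]
        blocks.setdefault(h, set()).add(ind)
    return Partition.from_blocks(ds.marker, ds.universe, blocks.values())


def marker_partition(ds: MarkerDataset) -> Partition:
    """sl-FFRs for diploid markers, haplogroups for haploid ones."""
    return delineate_sl_ffrs(ds) if ds.ploidy == 2 else haplogroups(ds)


@dataclass
class Haploweb:
    """A haplonet annotated with co-occurrence links and pool membership."""

    network: HaplotypeNetwork
    links: list[CooccurrenceLink]
    pools: list[frozenset[str]]

    @property
    def pool_of(self) -> dict[str, int]:
        return {h: i for i, pool in enumerate(self.pools) for h in pool}


def build_haploweb(
    net: HaplotypeNetwork,
    links: Sequence[CooccurrenceLink],
    pools: Sequence[frozenset[str]],
) -> Haploweb:
    """Compose network, links and pools, checking referential integrity."""
    observed = {n.hap_id for n in net.observed_nodes}
    for link in links:
        for h in (link.hap_u, link.hap_v):
            if h not in observed:
                raise ConsistencyError(
                    f"co-occurrence link endpoint {h!r} is not an observed "
                    f"node of the {net.marker!r} network"
                )
    pooled = set().union(*pools) if pools else set()
    if pooled - observed:
        raise ConsistencyError(
            f"pool members {sorted(pooled - observed)} missing from network"
        )
    return Haploweb(net, list(links), list(pools))


def write_partitions(partitions: Iterable[Partition], path: str | Path) -> None:
    """TSV twin of the boxed FFR lists: marker, block index, size, members."""
    rows = []
    for p in partitions:
        for i, b in enumerate(p.blocks, start=1):
            rows.append(
                {
                    "marker": p.label,
                    "block_index": i,
                    "block_size": len(b),
                    "members": ",".join(sorted(b)),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
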