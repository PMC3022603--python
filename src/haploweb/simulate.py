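"""Synthetic multi-marker datasets with known species truth.

The generator realises the regime in which allele-pool delimitation is
meaningful: reproductively isolated species whose allele pools are mutually
exclusive at every marker but need not be reciprocally monophyletic.  Each
species/marker pool follows a star genealogy — a species ancestor sequence
plus independent mutations per haplotype — which keeps within- and
between-pool distances analysable in closed form (mutation positions are
drawn without replacement per haplotype, so there is no back-mutation within
a haplotype).  Species ancestors are mutated at disjoint position sets, which
guarantees pools cannot collide; the generator asserts pairwise ancestor
distances of at least ``2 * intra_mutations + 1`` so that even maximally
diverged pool members of different species remain distinct.

Diploid genotypes are two independent draws from the species' haplotype
frequencies (Hardy–Weinberg); haploid (organelle-like) markers get one draw.
Haplotype frequencies are Dirichlet-distributed with a configurable
concentration: 1.0 (default) yields realistically skewed pools, larger values
more even ones.

Three contamination scenarios can be injected after generation: F1 hybrids
(one allele from each parent species' pool at every diploid marker),
single-marker introgression (one allele of one individual replaced by an
other-species haplotype), and shared ancestral polymorphism (one haplotype
handed to an individual of the other species, so the very same allele spans
the species boundary).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .io_model import (
    HaplotypeTable,
    MarkerDataset,
    SequenceRecord,
    collapse_haplotypes,
    write_genotype_table,
)
from .webffr import Partition, write_partitions

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int = 2
    individuals_per_species: int = 20
    markers: tuple[tuple[str, int], ...] = (("nuc1", 2), ("nuc2", 2), ("mt", 1))
    seq_length: int = 200
    intra_haplotypes_per_species_per_marker: int = 4
    intra_mutations: int = 2
    inter_mutations: int = 8
    allele_freq_concentration: float = 1.0
    f1_hybrid_count: int = 0
    introgressed_allele_count: int = 0
    introgression_marker: str | None = None
    shared_ancestral_count: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ConfigError("need at least one species")
        if self.individuals_per_species < 1:
            raise ConfigError("need at least one individual per species")
        if not self.markers:
            raise ConfigError("need at least one marker")
        for name, ploidy in self.markers:
            if ploidy not in (1, 2):
                raise ConfigError(f"marker {name!r}: ploidy must be 1 or 2")
        if self.intra_haplotypes_per_species_per_marker < 1:
            raise ConfigError("need at least one haplotype per pool")
        if 2 * self.inter_mutations < 2 * self.intra_mutations + 1:
            raise ConfigError(
                "inter_mutations too small: species ancestors must differ at "
                f">= {2 * self.intra_mutations + 1} positions to keep pools "
                "mutually exclusive"
            )
        if self.n_species * self.inter_mutations > self.seq_length:
            raise ConfigError(
                f"seq_length {self.seq_length} cannot host "
                f"{self.n_species} x {self.inter_mutations} species-specific "
                "mutated positions"
            )
        if self.intra_mutations > self.seq_length:
            raise ConfigError("seq_length cannot host intra_mutations")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @staticmethod
    def from_file(path: str | Path) -> "SimConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of config fields")
        known = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
        if "markers" in data:
            data["markers"] = tuple((str(n), int(p)) for n, p in data["markers"])
        cfg = SimConfig(**data)
        cfg.validate()
        return cfg


def sufficient_sampling_config(seed: int = 0) -> SimConfig:
    """The well-sampled two-species regime used for recovery checks.

    20 individuals and 3 haplotypes per species pool, with a high Dirichlet
    concentration so every pool haplotype has a non-negligible expected
    sample count — operationally what "sufficient sampling of the allele
    pool" means: each haplotype is expected many times and heterozygotes
    chain the pool together.
    """
    return SimConfig(
        n_species=2,
        individuals_per_species=20,
        intra_haplotypes_per_species_per_marker=3,
        allele_freq_concentration=8.0,
        seed=seed,
    )


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator):
    out = seq.copy()
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


@dataclass
class _Pool:
    """Per species and marker: haplotype sequences and their frequencies."""

    species: str
    marker: str
    sequences: list[str]
    freqs: np.ndarray


def _build_pools(cfg: SimConfig, rng: np.random.Generator) -> dict[str, list[_Pool]]:
    """Species ancestor + star-genealogy haplotypes for every marker."""
    pools: dict[str, list[_Pool]] = {name: [] for name, _ in cfg.markers}
    for marker, _ploidy in cfg.markers:
        root = rng.choice(_BASES, size=cfg.seq_length)
        # disjoint species-specific mutated position sets
        all_pos = rng.permutation(cfg.seq_length)
        for s in range(cfg.n_species):
            species = f"sp{s + 1}"
            pos = all_pos[s * cfg.inter_mutations : (s + 1) * cfg.inter_mutations]
            ancestor = _mutate(root, pos, rng)
            haps: list[str] = []
            tries = 0
            while len(haps) < cfg.intra_haplotypes_per_species_per_marker:
                tries += 1
                if tries > 100 * cfg.intra_haplotypes_per_species_per_marker:
                    raise ConfigError(
                        f"cannot draw distinct haplotypes for {species}/{marker}; "
                        "increase seq_length or intra_mutations"
                    )
                if not haps and cfg.intra_mutations == 0:
                    haps.append("".join(ancestor))
                    break
                mut_pos = rng.choice(
                    cfg.seq_length, size=cfg.intra_mutations, replace=False
                )
                hap = "".join(_mutate(ancestor, mut_pos, rng))
                if hap not in haps:
                    haps.append(hap)
                if cfg.intra_mutations == 0:
                    break
            freqs = rng.dirichlet(
                [cfg.allele_freq_concentration] * len(haps)
            )
            pools[marker].append(_Pool(species, marker, haps, freqs))
    # mutual exclusivity is guaranteed by construction; assert it anyway
    for marker, plist in pools.items():
        for i, a in enumerate(plist):
            for b in plist[i + 1 :]:
                shared = set(a.sequences) & set(b.sequences)
                assert not shared, (
                    f"species pools collided at {marker}: {len(shared)} shared"
                )
    return pools


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[list[tuple[HaplotypeTable, MarkerDataset]], Partition]:
    """Generate genotypes for every marker plus the true species partition.

    Deterministic given ``cfg.seed``; anomalies configured in ``cfg`` are
    applied via :func:`inject_anomalies` before returning.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pools = _build_pools(cfg, rng)

    width = len(str(cfg.n_species * cfg.individuals_per_species))
    individuals = [
        (f"sp{s + 1}", f"sp{s + 1}_ind{i + 1:0{width}d}")
        for s in range(cfg.n_species)
        for i in range(cfg.individuals_per_species)
    ]

    pairs: list[tuple[HaplotypeTable, MarkerDataset]] = []
    for marker, ploidy in cfg.markers:
        records: list[SequenceRecord] = []
        by_species = {p.species: p for p in pools[marker]}
        for species, ind in individuals:
            pool = by_species[species]
            draws = rng.choice(len(pool.sequences), size=ploidy, p=pool.freqs)
            for j, k in enumerate(draws):
                suffix = "_a" if j == 0 else "_b"
                records.append(
                    SequenceRecord(
                        f"{ind}{suffix}" if ploidy == 2 else ind,
                        ind,
                        marker,
                        pool.sequences[k],
                    )
                )
        pairs.append(collapse_haplotypes(records, ploidy))

    truth = Partition.from_blocks(
        "species-truth",
        [ind for _, ind in individuals],
        [
            {ind for sp, ind in individuals if sp == f"sp{s + 1}"}
            for s in range(cfg.n_species)
        ],
    )
    if cfg.f1_hybrid_count or cfg.introgressed_allele_count or cfg.shared_ancestral_count:
        pairs, truth = inject_anomalies(pairs, truth, cfg)
    return pairs, truth


# ---------------------------------------------------------------------------
# anomaly injection


def _species_haps(
    table: HaplotypeTable, ds: MarkerDataset, truth: Partition
) -> dict[frozenset[str], list[str]]:
    """hap_id pools per truth block (hap assigned to the block of its carriers)."""
    out: dict[frozenset[str], list[str]] = {b: [] for b in truth.blocks}
    for e in table.entries:
        blocks = {truth.block_of(m) for m in e.members if m in set(truth.universe)}
        if len(blocks) == 1:
            out[next(iter(blocks))].append(e.hap_id)
    return out


def _rebuild(
    table: HaplotypeTable, ds: MarkerDataset
) -> tuple[HaplotypeTable, MarkerDataset]:
    """Re-collapse after editing genotypes so counts/members stay consistent."""
    seq = {e.hap_id: e.sequence for e in table.entries}
    records = []
    for ind in ds.universe:
        g = ds.genotypes[ind]
        for j, h in enumerate(g):
            suffix = ("_a", "_b")[j] if ds.ploidy == 2 else ""
            records.append(SequenceRecord(f"{ind}{suffix}", ind, ds.marker, seq[h]))
    return collapse_haplotypes(records, ds.ploidy)


def inject_anomalies(
    pairs: Sequence[tuple[HaplotypeTable, MarkerDataset]],
    truth: Partition,
    cfg: SimConfig,
) -> tuple[list[tuple[HaplotypeTable, MarkerDataset]], Partition]:
    """Apply the configured contamination scenarios (seeded, reproducible).

    Returns rebuilt datasets and the (possibly extended) truth partition:
    F1 hybrids are added to the first parent's block, the common convention
    for organelle-typed vouchers (they carry that parent's haploid marker).
    """
    cfg.validate()
    if cfg.n_species < 2:
        raise ConfigError("anomalies require at least two species")
    rng = np.random.default_rng([cfg.seed, 913])
    tables = {ds.marker: table for table, ds in pairs}
    datasets = {ds.marker: ds for _, ds in pairs}
    genotypes = {m: dict(ds.genotypes) for m, ds in datasets.items()}
    universe = list(pairs[0][1].universe)
    truth_blocks = [set(b) for b in truth.blocks]

    pools_by_marker = {
        m: _species_haps(tables[m], datasets[m], truth) for m in datasets
    }

    def pool_for(marker: str, block_idx: int) -> list[str]:
        haps = pools_by_marker[marker][truth.blocks[block_idx]]
        if not haps:
            raise ConfigError(
                f"no species-private haplotypes left at {marker!r} to draw from"
            )
        return haps

    # --- F1 hybrids -------------------------------------------------------
    for h in range(cfg.f1_hybrid_count):
        sa, sb = rng.choice(len(truth.blocks), size=2, replace=False)
        hyb = f"hyb{h + 1}"
        for marker, ds in datasets.items():
            if ds.ploidy == 2:
                a = rng.choice(pool_for(marker, sa))
                b = rng.choice(pool_for(marker, sb))
                genotypes[marker][hyb] = tuple(sorted((a, b)))
            else:
                genotypes[marker][hyb] = (rng.choice(pool_for(marker, sa)),)
        universe.append(hyb)
        truth_blocks[sa].add(hyb)

    # --- single-marker introgression -------------------------------------
    diploid_markers = [m for m, ds in datasets.items() if ds.ploidy == 2]
    for _ in range(cfg.introgressed_allele_count):
        marker = cfg.introgression_marker or (
            diploid_markers[0] if diploid_markers else next(iter(datasets))
        )
        if marker not in datasets:
            raise ConfigError(f"unknown introgression marker {marker!r}")
        sa, sb = rng.choice(len(truth.blocks), size=2, replace=False)
        recipients = sorted(truth.blocks[sa])
        ind = recipients[rng.integers(len(recipients))]
        donor = rng.choice(pool_for(marker, sb))
        g = list(genotypes[marker][ind])
        g[rng.integers(len(g))] = donor
        genotypes[marker][ind] = tuple(sorted(g))

    # --- shared ancestral haplotype ---------------------------------------
    for _ in range(cfg.shared_ancestral_count):
        markers = sorted(datasets)
        marker = markers[rng.integers(len(markers))]
        sa, sb = rng.choice(len(truth.blocks), size=2, replace=False)
        shared = rng.choice(pool_for(marker, sa))
        recipients = sorted(truth.blocks[sb] - {i for i in universe if i.startswith("hyb")})
        ind = recipients[rng.integers(len(recipients))]
        g = list(genotypes[marker][ind])
        g[rng.integers(len(g))] = shared
        genotypes[marker][ind] = tuple(sorted(g))

    new_pairs = []
    for marker, ds in datasets.items():
        new_ds = MarkerDataset(marker, ds.ploidy, genotypes[marker], tuple(universe))
        new_pairs.append(_rebuild(tables[marker], new_ds))
    new_truth = Partition.from_blocks(truth.label, universe, truth_blocks)
    return new_pairs, new_truth


# ---------------------------------------------------------------------------
# export


def write_dataset(
    pairs: Sequence[tuple[HaplotypeTable, MarkerDataset]],
    truth: Partition,
    cfg: SimConfig,
    outdir: str | Path,
) -> None:
    """Emit the formats the readers consume: per-marker FASTA, genotype TSV,
    truth partition TSV and the config as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for table, ds in pairs:
        seq = {e.hap_id: e.sequence for e in table.entries}
        lines = []
        for ind in ds.universe:
            for j, h in enumerate(ds.genotypes[ind]):
                suffix = ("_a", "_b")[j] if ds.ploidy == 2 else ""
                lines.append(f">{ind}{suffix}")
                lines.append(seq[h])
        (outdir / f"{ds.marker}.fasta").write_text("\n".join(lines) + "\n")
    write_genotype_table(pairs, outdir / "genotypes.tsv")
    write_partitions([truth], outdir / "truth.tsv")
    cfg.to_json(outdir / "sim_config.json")
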