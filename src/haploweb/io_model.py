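"""Domain types and readers/writers for phased allele data.

The package works from *phased* per-marker alignments: for a diploid marker
every individual contributes its two allelic sequences (one for homozygotes is
tolerated and interpreted as two identical copies); for a haploid marker, one
sequence per individual.  Sequences are collapsed into distinct haplotypes by
exact, case-insensitive string identity — alignment gaps count as a fifth
character state, so two sequences differing only in gap placement are distinct
haplotypes.  Ambiguity codes are kept verbatim and matched exactly.

Two input formats are supported:

* aligned FASTA, one file per marker, with the individual id recovered from
  each header via a configurable regular expression (by default a trailing
  ``_a``/``_b``/``_1``/``_2``/``/1``/``/2`` token is stripped);
* a genotype TSV with columns ``individual  marker  allele_1  allele_2``,
  carrying either raw sequences or pre-assigned haplotype labels, with an
  empty ``allele_2`` denoting a haploid marker.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    DuplicateRecordError,
    FormatError,
    MultiplicityError,
    UniverseMismatchError,
)

logger = logging.getLogger(__name__)

#: characters beyond A/C/G/T/N/- that may legitimately appear in alignments
IUPAC_AMBIGUITY = set("RYSWKMBDHV")
_SEQ_CHARS = set("ACGTUN-") | IUPAC_AMBIGUITY

#: default rule to turn a FASTA header into an individual id: take the first
#: whitespace-delimited word and strip one trailing phase token
DEFAULT_ID_RULE = r"(.+?)(?:_a|_b|_1|_2|/1|/2)?$"


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned allelic sequence attributed to an individual."""

    seq_id: str
    individual_id: str
    marker: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.seq_id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class HaplotypeEntry:
    hap_id: str
    sequence: str
    count: int
    members: frozenset[str]


@dataclass
class HaplotypeTable:
    """Distinct sequences of one marker with their multiplicities.

    ``count`` is the number of input sequence records collapsed into the
    haplotype; ``members`` the individuals harbouring it (what node diameters
    are proportional to in drawings).
    """

    marker: str
    entries: list[HaplotypeEntry]

    def __post_init__(self):
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise FormatError(f"duplicate sequences in haplotype table {self.marker!r}")
        ids = [e.hap_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate hap_ids in haplotype table {self.marker!r}")

    @property
    def hap_ids(self) -> list[str]:
        return [e.hap_id for e in self.entries]

    def sequence_of(self, hap_id: str) -> str:
        return self._by_id[hap_id].sequence

    def entry(self, hap_id: str) -> HaplotypeEntry:
        return self._by_id[hap_id]

    @property
    def _by_id(self) -> dict[str, HaplotypeEntry]:
        return {e.hap_id: e for e in self.entries}


@dataclass
class MarkerDataset:
    """Genotypes of one marker: individual -> multiset of haplotype ids."""

    marker: str
    ploidy: int
    genotypes: dict[str, tuple[str, ...]]  # values sorted, length == ploidy
    universe: tuple[str, ...]

    def __post_init__(self):
        if self.ploidy not in (1, 2):
            raise FormatError(f"ploidy must be 1 or 2, got {self.ploidy}")
        if set(self.genotypes) != set(self.universe):
            raise FormatError(f"genotypes/universe mismatch for {self.marker!r}")
        for ind, alleles in self.genotypes.items():
            if len(alleles) != self.ploidy:
                raise MultiplicityError(
                    f"{ind!r} has {len(alleles)} alleles at {self.marker!r}, "
                    f"expected {self.ploidy}"
                )
        self.genotypes = {i: tuple(sorted(a)) for i, a in self.genotypes.items()}

    def is_heterozygote(self, individual: str) -> bool:
        g = self.genotypes[individual]
        return len(set(g)) > 1

    @property
    def heterozygotes(self) -> list[str]:
        return [i for i in self.universe if self.is_heterozygote(i)]

    @property
    def homozygotes(self) -> list[str]:
        return [i for i in self.universe if not self.is_heterozygote(i)]

    def all_hap_ids(self) -> list[str]:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for ind in self.universe:
            for h in self.genotypes[ind]:
                seen.setdefault(h)
        return list(seen)


def _natural_hap_key(hap_id: str):
    m = re.fullmatch(r"([a-zA-Z]*)(\d+)", hap_id)
    return (m.group(1), int(m.group(2))) if m else (hap_id, 0)


def collapse_haplotypes(
    records: Sequence[SequenceRecord], ploidy: int
) -> tuple[HaplotypeTable, MarkerDataset]:
    """Collapse aligned records into distinct haplotypes and genotypes.

    Identity is exact case-insensitive string equality, gaps included.
    Haplotype ids ``h1, h2, ...`` are assigned in order of first appearance
    after sorting records by ``seq_id``, so the labelling is byte-stable
    across runs and independent of input order.
    """
    if not records:
        raise FormatError("no sequence records to collapse")
    markers = {r.marker for r in records}
    if len(markers) != 1:
        raise FormatError(f"records span several markers: {sorted(markers)}")
    marker = markers.pop()

    length = len(records[0].sequence)
    for r in records:
        if len(r.sequence) != len(records[0].sequence):
            raise AlignmentLengthError(
                f"sequence {r.seq_id!r} has length {len(r.sequence)}, "
                f"expected {length} (marker {marker!r} must be aligned)"
            )
        ambig = set(r.sequence) & IUPAC_AMBIGUITY
        if ambig:
            logger.warning(
                "record %s contains ambiguity codes %s; collapsed by exact "
                "match only",
                r.seq_id,
                "".join(sorted(ambig)),
            )

    ordered = sorted(records, key=lambda r: r.seq_id)
    hap_of_seq: dict[str, str] = {}
    for r in ordered:
        if r.sequence not in hap_of_seq:
            hap_of_seq[r.sequence] = f"h{len(hap_of_seq) + 1}"

    by_individual: "OrderedDict[str, list[SequenceRecord]]" = OrderedDict()
    for r in ordered:
        by_individual.setdefault(r.individual_id, []).append(r)

    genotypes: dict[str, tuple[str, ...]] = {}
    for ind, recs in by_individual.items():
        if len(recs) > ploidy:
            raise MultiplicityError(
                f"individual {ind!r} has {len(recs)} sequences at {marker!r} "
                f"but ploidy is {ploidy}"
            )
        haps = [hap_of_seq[r.sequence] for r in recs]
        if len(recs) < ploidy:
            if ploidy == 2 and len(recs) == 1:
                logger.warning(
                    "individual %s provided a single sequence at diploid "
                    "marker %s; assumed homozygote",
                    ind,
                    marker,
                )
                haps = haps * 2
            else:
                raise MultiplicityError(
                    f"individual {ind!r} has {len(recs)} sequences at "
                    f"{marker!r}, expected {ploidy}"
                )
        genotypes[ind] = tuple(sorted(haps))

    counts: Counter[str] = Counter(hap_of_seq[r.sequence] for r in ordered)
    members: dict[str, set[str]] = {h: set() for h in hap_of_seq.values()}
    for ind, haps in genotypes.items():
        for h in haps:
            members[h].add(ind)

    entries = [
        HaplotypeEntry(h, seq, counts[h], frozenset(members[h]))
        for seq, h in hap_of_seq.items()
    ]
    entries.sort(key=lambda e: _natural_hap_key(e.hap_id))
    table = HaplotypeTable(marker=marker, entries=entries)
    ds = MarkerDataset(
        marker=marker,
        ploidy=ploidy,
        genotypes=genotypes,
        universe=tuple(by_individual),
    )
    return table, ds


def read_phased_fasta(
    path: str | Path,
    marker: str,
    ploidy: int,
    id_rule: str = DEFAULT_ID_RULE,
) -> tuple[HaplotypeTable, MarkerDataset]:
    """Read one marker's aligned, phased FASTA file.

    ``id_rule`` is a regex with one capture group applied (fullmatch) to the
    first whitespace-delimited word of each header to obtain the individual id.
    """
    path = Path(path)
    pattern = re.compile(id_rule)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        word = rec.id
        m = pattern.fullmatch(word)
        if not m or not m.group(1):
            raise FormatError(
                f"header {word!r} in {path} does not match id rule {id_rule!r}"
            )
        records.append(
            SequenceRecord(
                seq_id=word,
                individual_id=m.group(1),
                marker=marker,
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return collapse_haplotypes(records, ploidy)


_GENOTYPE_COLUMNS = ["individual", "marker", "allele_1", "allele_2"]


def _looks_like_sequence(value: str) -> bool:
    return bool(value) and set(value.upper()) <= _SEQ_CHARS


def read_genotype_table(path: str | Path) -> list[tuple[HaplotypeTable, MarkerDataset]]:
    """Read a genotype TSV into one (table, dataset) pair per marker.

    All markers must cover the same set of individuals; haploid markers leave
    ``allele_2`` empty on every row.  A missing ``allele_2`` on a marker that
    is otherwise diploid is parsed as a homozygote (with a warning).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _GENOTYPE_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_GENOTYPE_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError(f"{path}: no genotype rows")

    dup = df.duplicated(subset=["individual", "marker"])
    if dup.any():
        pairs = df.loc[dup, ["individual", "marker"]].values.tolist()
        raise DuplicateRecordError(f"{path}: duplicate (individual, marker) rows: {pairs}")

    universe = list(dict.fromkeys(df["individual"]))
    markers = list(dict.fromkeys(df["marker"]))

    out: list[tuple[HaplotypeTable, MarkerDataset]] = []
    for marker in markers:
        sub = df[df["marker"] == marker]
        present = list(dict.fromkeys(sub["individual"]))
        missing = [i for i in universe if i not in set(present)]
        if missing:
            raise UniverseMismatchError(
                f"{path}: marker {marker!r} lacks rows for individuals {missing}",
                missing={marker: missing},
            )
        ploidy = 2 if (sub["allele_2"] != "").any() else 1
        records: list[SequenceRecord] = []
        for _, row in sub.iterrows():
            a1, a2 = row["allele_1"], row["allele_2"]
            if not a1:
                raise FormatError(
                    f"{path}: empty allele_1 for {row['individual']!r}/{marker!r}"
                )
            records.append(
                SequenceRecord(
                    f"{row['individual']}_a", row["individual"], marker, a1
                )
            )
            if ploidy == 2 and a2:
                records.append(
                    SequenceRecord(
                        f"{row['individual']}_b", row["individual"], marker, a2
                    )
                )
        if any(not _looks_like_sequence(r.sequence) for r in records):
            # label mode: cells are pre-assigned haplotype names, collapsed by
            # identity; pad to a common length so alignment checks pass
            width = max(len(r.sequence) for r in records)
            records = [
                SequenceRecord(r.seq_id, r.individual_id, r.marker,
                               r.sequence.ljust(width, "."))
                for r in records
            ]
        out.append(collapse_haplotypes(records, ploidy))

    # collapse_haplotypes orders the universe by first appearance within the
    # marker; normalize all datasets to the file-wide individual order
    normalized = []
    for table, ds in out:
        normalized.append(
            (table, MarkerDataset(ds.marker, ds.ploidy, ds.genotypes, tuple(universe)))
        )
    return normalized


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    rows = [
        {
            "hap_id": e.hap_id,
            "marker": table.marker,
            "count": e.count,
            "members": ",".join(sorted(e.members)),
            "sequence": e.sequence,
        }
        for e in table.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_genotype_table(
    pairs: Iterable[tuple[HaplotypeTable, MarkerDataset]], path: str | Path
) -> None:
    """Write datasets back to the genotype TSV format (round-trip safe)."""
    rows = []
    pairs = list(pairs)
    for table, ds in pairs:
        seq = {e.hap_id: e.sequence for e in table.entries}
        for ind in ds.universe:
            g = ds.genotypes[ind]
            rows.append(
                {
                    "individual": ind,
                    "marker": ds.marker,
                    "allele_1": seq[g[0]],
                    "allele_2": seq[g[1]] if ds.ploidy == 2 else "",
                }
            )
    # keep one row per (individual, marker), individuals in universe order
    universe = pairs[0][1].universe if pairs else ()
    df = pd.DataFrame(rows)
    df["__i"] = df["individual"].map({u: i for i, u in enumerate(universe)})
    df = df.sort_values(["__i"], kind="stable").drop(columns="__i")
    df.to_csv(path, sep="\t", index=False)
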