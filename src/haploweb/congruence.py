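"""Multi-marker congruence via bipartition scoring and partition lattice ops.

Each marker's sl-FFR (or haplogroup) partition supports a set of bipartitions
of the sample set: the splits obtainable by pooling its blocks into two
complementary groups.  A partition with k blocks supports 2^(k-1) - 1 such
non-trivial bipartitions.  Scoring every bipartition by the fraction of
independent datasets supporting it quantifies the congruence between markers;
bipartitions above a support cutoff (default 50%, strict) are reconciled into
a final grouping — the putative species.

Two classic lattice operations complement the scores: the *join* (finest
common coarsening, Doyle's multi-locus FFRs — transitive closure of "same
block in at least one marker") and the *meet* (coarsest common refinement,
whose blocks are the intersections of one block per marker).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    EnumerationCapError,
    FormatError,
    IncompatibleBipartitionsError,
    UniverseMismatchError,
)
from .webffr import Partition, _UnionFind

#: maximum number of blocks for exhaustive bipartition enumeration
DEFAULT_ENUMERATION_CAP = 20


@dataclass(frozen=True)
class Bipartition:
    """A split of the universe into two complementary non-empty groups.

    Canonical form stores the side NOT containing the lexicographically
    smallest individual, so each unordered split has a unique representation.
    """

    universe: tuple[str, ...]
    side: frozenset[str]

    @staticmethod
    def from_side(universe: Sequence[str], side: Iterable[str]) -> "Bipartition":
        u = tuple(universe)
        s = frozenset(side)
        if not s or s >= set(u):
            raise FormatError("bipartition side must be a non-empty proper subset")
        if not s <= set(u):
            raise FormatError("bipartition side contains unknown individuals")
        if min(u) in s:
            s = frozenset(u) - s
        return Bipartition(u, s)

    def __post_init__(self):
        if not self.side or self.side >= set(self.universe):
            raise FormatError("bipartition side must be a non-empty proper subset")
        if min(self.universe) in self.side:
            raise FormatError("bipartition side is not canonical")

    @property
    def complement(self) -> frozenset[str]:
        return frozenset(self.universe) - self.side

    def as_partition(self, label: str = "bipartition") -> Partition:
        return Partition.from_blocks(
            label, self.universe, [self.side, self.complement]
        )

    def describe(self) -> str:
        small = min((self.side, self.complement), key=lambda s: (len(s), sorted(s)))
        return "+".join(sorted(small)) + " vs. all others"


def _check_same_universe(partitions: Sequence[Partition]) -> tuple[str, ...]:
    universes = {frozenset(p.universe) for p in partitions}
    if len(universes) != 1:
        detail = {p.label: sorted(set().union(*universes) - set(p.universe))
                  for p in partitions}
        raise UniverseMismatchError(
            "bipartition scoring only works if sl-FFRs for all markers are "
            f"delineated from the same set of individuals; missing: {detail}",
            missing=detail,
        )
    return partitions[0].universe


def partition_bipartitions(
    p: Partition, cap: int = DEFAULT_ENUMERATION_CAP
) -> set[Bipartition]:
    """All non-trivial bipartitions whose sides are unions of p's blocks.

    Exactly 2^(k-1) - 1 of them for k blocks; the empty set for k = 1.
    """
    if p.k > cap:
        raise EnumerationCapError(
            f"partition {p.label!r} has {p.k} blocks; enumerating "
            f"2^{p.k - 1}-1 bipartitions exceeds the cap of {cap} blocks — "
            "raise `cap` explicitly if this is intended"
        )
    if p.k == 1:
        return set()
    smallest = min(p.universe)
    anchor = p.block_of(smallest)
    others = [b for b in p.blocks if b is not anchor]
    out: set[Bipartition] = set()
    for mask in range(1, 1 << len(others)):
        side: set[str] = set()
        for i, b in enumerate(others):
            if mask >> i & 1:
                side |= b
        out.add(Bipartition.from_side(p.universe, side))
    return out


def supports(p: Partition, b: Bipartition) -> bool:
    """True iff every block of ``p`` lies entirely within one side of ``b``."""
    if set(p.universe) != set(b.universe):
        raise UniverseMismatchError(
            f"partition {p.label!r} and bipartition are over different universes"
        )
    return all(block <= b.side or block.isdisjoint(b.side) for block in p.blocks)


def _percent_half_up(fraction: Fraction) -> int:
    return math.floor(fraction * 100 + Fraction(1, 2))


@dataclass(frozen=True)
class SupportRow:
    bipartition: Bipartition
    supported_by: frozenset[str]
    support: Fraction

    @property
    def percent(self) -> int:
        return _percent_half_up(self.support)


@dataclass
class SupportTable:
    """Machine twin of the bipartition-support table (one row per split)."""

    rows: list[SupportRow]
    labels: tuple[str, ...]  # the M independent datasets, in input order
    universe: tuple[str, ...]

    @property
    def n_datasets(self) -> int:
        return len(self.labels)


def score_bipartitions(
    partitions: Sequence[Partition],
    cap: int = DEFAULT_ENUMERATION_CAP,
    restrict_to_common: bool = False,
) -> SupportTable:
    """Score every bipartition supported by >= 1 input partition.

    Support is the exact fraction of the M input datasets supporting the
    split (each partition counts as one independent dataset).  With
    ``restrict_to_common`` the partitions are first restricted to the
    individuals present in all of them instead of raising on a mismatch.
    """
    if not partitions:
        raise FormatError("need at least one partition to score")
    labels = [p.label for p in partitions]
    if len(set(labels)) != len(labels):
        raise FormatError(f"partition labels are not unique: {labels}")
    if restrict_to_common:
        common = frozenset.intersection(
            *[frozenset(p.universe) for p in partitions]
        )
        if not common:
            raise UniverseMismatchError("no individuals shared by all markers")
        partitions = [
            Partition.from_blocks(
                p.label,
                [i for i in p.universe if i in common],
                [b & common for b in p.blocks if b & common],
            )
            for p in partitions
        ]
    universe = _check_same_universe(partitions)

    supported_by: dict[Bipartition, set[str]] = {}
    for p in partitions:
        for b in partition_bipartitions(p, cap=cap):
            supported_by.setdefault(b, set()).add(p.label)

    m = len(partitions)
    rows = [
        SupportRow(b, frozenset(who), Fraction(len(who), m))
        for b, who in supported_by.items()
    ]
    rows.sort(key=lambda r: (-r.support, sorted(r.bipartition.side)))
    return SupportTable(rows, tuple(labels), tuple(universe))


def ml_ffr_join(partitions: Sequence[Partition], label: str = "ml-FFR") -> Partition:
    """Finest common coarsening: transitive closure of block co-membership.

    This is Doyle's multi-locus FFR rule — individuals sharing a block in at
    least one marker end up together.
    """
    if not partitions:
        raise FormatError("need at least one partition to join")
    universe = _check_same_universe(partitions)
    uf = _UnionFind(universe)
    for p in partitions:
        for block in p.blocks:
            members = sorted(block)
            for other in members[1:]:
                uf.union(members[0], other)
    return Partition.from_blocks(label, universe, uf.groups())


def partition_meet(partitions: Sequence[Partition], label: str = "meet") -> Partition:
    """Coarsest common refinement: non-empty intersections of blocks."""
    if not partitions:
        raise FormatError("need at least one partition to meet")
    universe = _check_same_universe(partitions)
    signature: dict[tuple[int, ...], set[str]] = {}
    for ind in universe:
        sig = tuple(
            next(i for i, b in enumerate(p.blocks) if ind in b) for p in partitions
        )
        signature.setdefault(sig, set()).add(ind)
    return Partition.from_blocks(label, universe, signature.values())


def compatible(a: Bipartition, b: Bipartition) -> bool:
    """Two splits are compatible iff some pair of opposite sides is disjoint."""
    sa, ca = a.side, a.complement
    sb, cb = b.side, b.complement
    return any(
        x.isdisjoint(y) for x in (sa, ca) for y in (sb, cb)
    )


@dataclass
class ReconciliationResult:
    kept: list[SupportRow]
    final: Partition
    threshold: Fraction


def reconcile(
    table: SupportTable,
    threshold: float | Fraction = Fraction(1, 2),
) -> ReconciliationResult:
    """Keep splits with support strictly above the cutoff and intersect them.

    The default cutoff of 50% (strict) drops 1/3-supported rows and keeps
    2/3-supported ones.  Kept bipartitions must be pairwise compatible;
    conflicts raise :class:`IncompatibleBipartitionsError` carrying the
    offending pairs — no silent resolution.  The final grouping is the meet
    of the kept bipartitions viewed as 2-block partitions (a single
    all-inclusive group when nothing is kept).
    """
    threshold = Fraction(threshold).limit_denominator(10**6)
    kept = [r for r in table.rows if r.support > threshold]
    conflicts = [
        (a, b)
        for i, a in enumerate(kept)
        for b in kept[i + 1 :]
        if not compatible(a.bipartition, b.bipartition)
    ]
    if conflicts:
        raise IncompatibleBipartitionsError(conflicts)
    if kept:
        final = partition_meet(
            [r.bipartition.as_partition(f"split{i + 1}") for i, r in enumerate(kept)],
            label="reconciled",
        )
    else:
        final = Partition.from_blocks("reconciled", table.universe, [table.universe])
    return ReconciliationResult(kept, final, threshold)


# ---------------------------------------------------------------------------
# writers


def _table_frame(table: SupportTable) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(table.rows, start=1):
        row = {"row": i, "bipartition": r.bipartition.describe()}
        for label in table.labels:
            row[label] = "yes" if label in r.supported_by else ""
        row["support"] = f"{r.percent}%"
        rows.append(row)
    return pd.DataFrame(rows)


def write_support_table_tsv(table: SupportTable, path: str | Path) -> None:
    _table_frame(table).to_csv(path, sep="\t", index=False)


def write_support_table_markdown(table: SupportTable, path: str | Path) -> None:
    df = _table_frame(table)
    df = df.replace({"yes": "√"})
    lines = [
        "| " + " | ".join(str(c) for c in df.columns) + " |",
        "| " + " | ".join("---" for _ in df.columns) + " |",
    ]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    Path(path).write_text("\n".join(lines) + "\n")


def write_support_table_json(table: SupportTable, path: str | Path) -> None:
    """JSON export keeping exact support fractions."""
    payload = {
        "datasets": list(table.labels),
        "n_individuals": len(table.universe),
        "rows": [
            {
                "side": sorted(r.bipartition.side),
                "supported_by": sorted(r.supported_by),
                "support": {
                    "numerator": r.support.numerator,
                    "denominator": r.support.denominator,
                },
                "percent": r.percent,
            }
            for r in table.rows
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
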