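"""The 74-sample *Pocillopora* worked example from Clipperton Island.

This module reconstructs, from the published partition structure alone, the
three marker groupings of the Clipperton coral survey (74 colonies, names
``05Clip001``–``05Clip103`` with gaps):

* ITS2 sl-FFRs: blocks of 55, 17, 1 and 1 individuals; the singletons are
  05Clip016 and 05Clip056;
* ATPSβ sl-FFRs: blocks of 57 and 17 individuals;
* combined mitochondrial (ORF + control region) haplogroups: blocks of 52,
  17, 3 and 2 individuals; the block of two is {05Clip048, 05Clip056} and
  the block of three is {05Clip027, 05Clip051, 05Clip100}.

The 17-individual block (here called ``B``) is the same across all three
markers — the published support table does not list its membership, so we
take the 17 lexicographically smallest sample names outside the six
individually named ones.  Bipartition scoring is invariant under renaming of
individuals, so every quantity computed from this fixture is independent of
that arbitrary choice (the test suite asserts this invariance).

The underlying sequences are deposited as GenBank FR729101–FR729473; they are
not needed here, since all congruence-level results follow from the partition
structure.
"""

from __future__ import annotations

from .webffr import Partition

#: the 74 collected colonies (suffix numbers of 05ClipNNN)
_SAMPLE_NUMBERS = (
    list(range(1, 4)) + [5, 6, 7] + list(range(12, 17)) + [18, 19, 21, 22]
    + list(range(26, 54)) + list(range(55, 65)) + list(range(79, 83))
    + [85, 86, 87, 89, 90] + list(range(92, 104))
)

#: individuals named explicitly in the published support table
NAMED = (
    "05Clip016",
    "05Clip027",
    "05Clip048",
    "05Clip051",
    "05Clip056",
    "05Clip100",
)

ITS2 = "ITS2"
ATPSB = "ATPSbeta"
MITO = "mtDNA"


def sample_names() -> list[str]:
    """The 74 sample ids, lexicographically sorted."""
    names = [f"05Clip{n:03d}" for n in _SAMPLE_NUMBERS]
    assert len(names) == 74
    return sorted(names)


def species_b_block() -> frozenset[str]:
    """The 17-individual block shared by all three markers."""
    pool = [n for n in sample_names() if n not in NAMED]
    return frozenset(pool[:17])


def marker_partitions() -> dict[str, Partition]:
    """The three marker partitions over the 74 samples."""
    universe = sample_names()
    b = species_b_block()
    rest = set(universe) - b

    its = Partition.from_blocks(
        ITS2,
        universe,
        [rest - {"05Clip016", "05Clip056"}, b, {"05Clip016"}, {"05Clip056"}],
    )
    atps = Partition.from_blocks(ATPSB, universe, [rest, b])
    mito_pair = {"05Clip048", "05Clip056"}
    mito_trio = {"05Clip027", "05Clip051", "05Clip100"}
    mito = Partition.from_blocks(
        MITO,
        universe,
        [rest - mito_pair - mito_trio, b, mito_trio, mito_pair],
    )
    return {ITS2: its, ATPSB: atps, MITO: mito}
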