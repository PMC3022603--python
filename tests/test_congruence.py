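"""Bipartition enumeration, scoring, lattice operations, reconciliation."""

import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploweb.congruence import (
    Bipartition,
    compatible,
    ml_ffr_join,
    partition_bipartitions,
    partition_meet,
    reconcile,
    score_bipartitions,
    supports,
    write_support_table_json,
    write_support_table_markdown,
    write_support_table_tsv,
)
from haploweb.errors import (
    EnumerationCapError,
    IncompatibleBipartitionsError,
    UniverseMismatchError,
)
from haploweb.webffr import Partition


def part(label, universe, *blocks):
    return Partition.from_blocks(label, universe, blocks)


def random_partition(rng, universe, label="p"):
    k = rng.randint(1, len(universe))
    blocks = [set() for _ in range(k)]
    for i, ind in enumerate(universe):
        target = i if i < k else rng.randrange(k)
        blocks[target].add(ind)
    return Partition.from_blocks(label, universe, blocks)


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 0), (2, 1), (3, 3), (4, 7)])
    def test_published_counts(self, k, expected):
        universe = [f"i{j}" for j in range(k + 2)]
        blocks = [{f"i{j}"} for j in range(k - 1)] + [set(universe[k - 1 :])]
        p = part("p", universe, *blocks)
        assert len(partition_bipartitions(p)) == expected

    def test_three_blocks_listed(self):
        p = part("p", "abc", {"a"}, {"b"}, {"c"})
        got = {frozenset(b.side) for b in partition_bipartitions(p)}
        assert got == {frozenset("b"), frozenset("c"), frozenset("bc")}

    def test_count_formula_matches_brute_force_over_individuals(self):
        rng = random.Random(2)
        for k in range(1, 13):
            n = k + rng.randint(0, 3)
            universe = [f"i{j:02d}" for j in range(n)]
            blocks = [{universe[j]} for j in range(k - 1)]
            blocks.append(set(universe[k - 1 :]))
            p = part("p", universe, *blocks)
            enumerated = partition_bipartitions(p)
            assert len(enumerated) == 2 ** (k - 1) - 1
            if n <= 12:
                # brute force over all canonical subsets of individuals
                smallest = min(universe)
                others = [i for i in universe if i != smallest]
                brute = 0
                for r in range(1, len(others) + 1):
                    for side in itertools.combinations(others, r):
                        b = Bipartition.from_side(universe, side)
                        ok = all(
                            blk <= b.side or blk.isdisjoint(b.side)
                            for blk in p.blocks
                        )
                        assert ok == (b in enumerated)
                        brute += ok
                assert brute == len(enumerated)

    def test_cap_guard(self):
        universe = [f"i{j:02d}" for j in range(25)]
        p = part("p", universe, *({u} for u in universe))
        with pytest.raises(EnumerationCapError):
            partition_bipartitions(p)
        small = part("q", universe[:5], *({u} for u in universe[:5]))
        with pytest.raises(EnumerationCapError):
            partition_bipartitions(small, cap=4)
        assert len(partition_bipartitions(small, cap=5)) == 15


class TestSupports:
    def test_examples(self):
        p = part("p", "abc", {"a", "b"}, {"c"})
        assert supports(p, Bipartition.from_side("abc", {"c"}))
        assert not supports(p, Bipartition.from_side("abc", {"b"}))

    def test_universe_mismatch(self):
        p = part("p", "ab", {"a"}, {"b"})
        with pytest.raises(UniverseMismatchError):
            supports(p, Bipartition.from_side("abc", {"c"}))

    def test_agrees_with_membership_in_enumeration(self):
        rng = random.Random(31)
        for _ in range(20):
            n = rng.randint(2, 8)
            universe = [f"i{j}" for j in range(n)]
            p = random_partition(rng, universe)
            enumerated = partition_bipartitions(p)
            smallest = min(universe)
            others = [i for i in universe if i != smallest]
            for r in range(1, len(others) + 1):
                for side in itertools.combinations(others, r):
                    b = Bipartition.from_side(universe, side)
                    assert supports(p, b) == (b in enumerated)


class TestScoring:
    def test_single_two_block_partition(self):
        p = part("m1", "abcd", {"a", "b"}, {"c", "d"})
        table = score_bipartitions([p])
        assert len(table.rows) == 1
        assert table.rows[0].percent == 100

    def test_identical_vs_different_splits(self):
        u = "abcd"
        p1 = part("m1", u, {"a", "b"}, {"c", "d"})
        p2 = part("m2", u, {"a", "b"}, {"c", "d"})
        assert len(score_bipartitions([p1, p2]).rows) == 1
        p3 = part("m3", u, {"a", "c"}, {"b", "d"})
        table = score_bipartitions([p1, p3])
        assert len(table.rows) == 2
        assert all(r.support == Fraction(1, 2) for r in table.rows)

    def test_percent_rounds_half_up(self):
        u = "abcdef"
        parts = [
            part("m1", u, {"a", "b", "c"}, {"d", "e", "f"}),
            part("m2", u, set("ab"), set("cdef")),
            part("m3", u, set("abcde"), {"f"}),
        ]
        table = score_bipartitions(parts)
        assert {r.percent for r in table.rows} == {33}
        assert {r.support for r in table.rows} == {Fraction(1, 3)}

    def test_universe_mismatch_raises_with_restrict_escape(self):
        p1 = part("m1", "abcd", set("ab"), set("cd"))
        p2 = part("m2", "abc", set("ab"), {"c"})
        with pytest.raises(UniverseMismatchError):
            score_bipartitions([p1, p2])
        table = score_bipartitions([p1, p2], restrict_to_common=True)
        assert len(table.universe) == 3
        assert [r.percent for r in table.rows] == [100]

    def test_invariant_under_individual_renaming(self):
        rng = random.Random(55)
        universe = [f"i{j:02d}" for j in range(10)]
        ps = [random_partition(rng, universe, f"m{j}") for j in range(3)]
        table = score_bipartitions(ps)
        renamed = {u: f"z{rng.random():.10f}" for u in universe}
        ps2 = [p.relabel(renamed) for p in ps]
        table2 = score_bipartitions(ps2)
        assert sorted(r.support for r in table.rows) == sorted(
            r.support for r in table2.rows
        )
        assert len(table.rows) == len(table2.rows)


class TestLattice:
    def test_join_single_input_identity(self):
        p = part("m", "abc", {"a"}, {"b", "c"})
        assert ml_ffr_join([p]).blocks == p.blocks

    def test_join_transitivity(self):
        u = "abc"
        j = ml_ffr_join([part("m1", u, {"a"}, {"b", "c"}),
                         part("m2", u, {"a", "b"}, {"c"})])
        assert j.blocks == (frozenset("abc"),)

    def test_meet_examples(self):
        u = "abc"
        p1 = part("m1", u, {"a", "b"}, {"c"})
        assert partition_meet([p1, p1]).blocks == p1.blocks
        p2 = part("m2", u, {"a"}, {"b", "c"})
        assert partition_meet([p1, p2]).block_sizes() == [1, 1, 1]

    def test_lattice_laws(self):
        rng = random.Random(8)
        universe = [f"i{j}" for j in range(9)]
        for _ in range(15):
            ps = [random_partition(rng, universe, f"m{j}") for j in range(3)]
            for op in (ml_ffr_join, partition_meet):
                abc = op([ps[0], ps[1], ps[2]])
                bca = op([ps[1], ps[2], ps[0]])
                assert set(abc.blocks) == set(bca.blocks)  # commutative
                assert set(op([ps[0], ps[0]]).blocks) == set(ps[0].blocks)  # idempotent
                two_step = op([op([ps[0], ps[1]], "t"), ps[2]])
                assert set(two_step.blocks) == set(abc.blocks)  # associative
            join, meet = ml_ffr_join(ps), partition_meet(ps)
            for p in ps:
                # join coarser than every input, meet finer
                for b in p.blocks:
                    assert any(b <= jb for jb in join.blocks)
                for mb in meet.blocks:
                    assert any(mb <= b for b in p.blocks)


class TestReconcile:
    def test_strict_threshold_drops_one_third(self):
        u = "abcdef"
        ps = [
            part("m1", u, set("abc"), set("def")),
            part("m2", u, set("abc"), set("def")),
            part("m3", u, set("ab"), set("cdef")),
        ]
        table = score_bipartitions(ps)
        res = reconcile(table, Fraction(1, 2))
        assert [r.support for r in res.kept] == [Fraction(2, 3)]
        assert set(res.final.block_sizes()) == {3}

    def test_empty_table_single_group(self):
        p = part("m1", "abc", set("abc"))
        table = score_bipartitions([p])  # k=1 -> no bipartitions
        res = reconcile(table)
        assert res.kept == []
        assert res.final.block_sizes() == [3]

    def test_conflict_detection_at_zero_threshold(self, clipperton_partitions):
        table = score_bipartitions(list(clipperton_partitions.values()))
        with pytest.raises(IncompatibleBipartitionsError) as err:
            reconcile(table, 0)
        assert len(err.value.conflicts) > 0
        # conflicts confirmed by brute force on the pair sides
        for a, b in err.value.conflicts:
            sa, sb = a.bipartition.side, b.bipartition.side
            ca, cb = a.bipartition.complement, b.bipartition.complement
            assert all(x & y for x in (sa, ca) for y in (sb, cb))

    def test_compatibility_predicate(self):
        u = "abcd"
        nested = (Bipartition.from_side(u, {"d"}), Bipartition.from_side(u, {"c", "d"}))
        assert compatible(*nested)
        crossing = (
            Bipartition.from_side(u, {"b", "c"}),
            Bipartition.from_side(u, {"c", "d"}),
        )
        assert not compatible(*crossing)


class TestClippertonFixture:
    def test_thirteen_rows_one_unanimous(self, clipperton_partitions):
        table = score_bipartitions(list(clipperton_partitions.values()))
        assert len(table.rows) == 13
        by_m = [len(r.supported_by) for r in table.rows]
        assert by_m.count(3) == 1 and by_m.count(2) == 0 and by_m.count(1) == 12
        assert table.rows[0].percent == 100
        assert all(r.percent == 33 for r in table.rows[1:])

    def test_reconciliation_two_species(self, clipperton_partitions):
        table = score_bipartitions(list(clipperton_partitions.values()))
        res = reconcile(table)
        assert len(res.kept) == 1
        assert res.final.block_sizes() == [57, 17]

    def test_nuclear_join(self, clipperton_partitions):
        j = ml_ffr_join(
            [clipperton_partitions["ITS2"], clipperton_partitions["ATPSbeta"]]
        )
        assert j.block_sizes() == [57, 17]

    def test_meet_isolates_05clip048(self, clipperton_partitions):
        m = partition_meet(list(clipperton_partitions.values()))
        assert m.block_sizes() == [51, 17, 3, 1, 1, 1]
        singles = {min(b) for b in m.blocks if len(b) == 1}
        assert "05Clip048" in singles

    def test_unanimous_row_is_two_block_coarsening_of_meet(self, clipperton_partitions):
        ps = list(clipperton_partitions.values())
        table = score_bipartitions(ps)
        top = table.rows[0]
        meet = partition_meet(ps)
        side = top.bipartition.side
        assert all(b <= side or b.isdisjoint(side) for b in meet.blocks)
        for p in ps:
            assert supports(p, top.bipartition)

    def test_fixture_invariant_to_block_b_choice(self):
        # the 17-individual block is unnamed in the published table; any
        # choice of its membership gives the same support profile
        from haploweb import clipperton

        universe = clipperton.sample_names()
        free = [n for n in universe if n not in clipperton.NAMED]
        rng = random.Random(99)
        base = score_bipartitions(list(clipperton.marker_partitions().values()))

        b_alt = frozenset(rng.sample(free, 17))
        rest = set(universe) - b_alt
        its = Partition.from_blocks(
            "ITS2", universe,
            [rest - {"05Clip016", "05Clip056"}, b_alt, {"05Clip016"}, {"05Clip056"}],
        )
        atps = Partition.from_blocks("ATPSbeta", universe, [rest, b_alt])
        pair = {"05Clip048", "05Clip056"}
        trio = {"05Clip027", "05Clip051", "05Clip100"}
        mito = Partition.from_blocks(
            "mtDNA", universe, [rest - pair - trio, b_alt, trio, pair]
        )
        alt = score_bipartitions([its, atps, mito])
        assert len(alt.rows) == len(base.rows) == 13
        assert sorted(r.support for r in alt.rows) == sorted(
            r.support for r in base.rows
        )
        assert reconcile(alt).final.block_sizes() == [57, 17]


class TestWriters:
    def test_tsv_markdown_json(self, tmp_path, clipperton_partitions):
        table = score_bipartitions(list(clipperton_partitions.values()))
        write_support_table_tsv(table, tmp_path / "t.tsv")
        write_support_table_markdown(table, tmp_path / "t.md")
        write_support_table_json(table, tmp_path / "t.json")
        md = (tmp_path / "t.md").read_text()
        assert md.count("100%") == 1 and md.count("33%") == 12
        top = md.splitlines()[2]
        assert top.count("√") == 3  # the unanimous row carries all three marks
        import json

        data = json.loads((tmp_path / "t.json").read_text())
        assert data["rows"][0]["support"] == {"numerator": 1, "denominator": 1}
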