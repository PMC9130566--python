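import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolparallel.io import GeneModel
from poolparallel.regions import (
    OutlierRegion,
    annotate_genes,
    merge_regions,
    shared_across,
    shared_polymorphism,
    shared_regions,
)
from poolparallel.scan import WindowStat


def win(scaffold, start, end, stat=1.0, index=1):
    return WindowStat(scaffold, index, 20, (start, end), stat)


def region(scaffold, start, end):
    return OutlierRegion(scaffold, start, end,
                         windows=[win(scaffold, start, end)])


class TestMergeRegions:
    def test_windows_within_20kb_merge(self):
        regs = merge_regions([win("s", 1000, 2000), win("s", 15000, 16000)])
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (1000, 16000)
        assert len(regs[0].windows) == 2

    def test_windows_beyond_20kb_stay_separate(self):
        regs = merge_regions([win("s", 1000, 2000), win("s", 42001, 43000)])
        assert len(regs) == 2

    def test_exact_boundary_gaps(self):
        # 20000 intervening bases merge; 20001 do not
        assert len(merge_regions([win("s", 1, 100), win("s", 20101, 20200)])) == 1
        assert len(merge_regions([win("s", 1, 100), win("s", 20102, 20200)])) == 2

    def test_single_window_region_equals_span(self):
        regs = merge_regions([win("s", 500, 700, stat=2.5)])
        assert (regs[0].start, regs[0].end) == (500, 700)
        assert regs[0].peak_stat == 2.5

    def test_different_scaffolds_never_merge(self):
        regs = merge_regions([win("s1", 1, 100), win("s2", 101, 200)])
        assert len(regs) == 2

    def test_merge_is_transitive(self):
        # a-b and b-c within gap, a-c not: all three merge
        regs = merge_regions([win("s", 1, 100), win("s", 15000, 15100),
                              win("s", 30000, 30100)])
        assert len(regs) == 1

    def test_peak_stat_is_max_over_windows(self):
        regs = merge_regions([win("s", 1, 100, stat=1.0),
                              win("s", 200, 300, stat=3.0),
                              win("s", 400, 500, stat=2.0)])
        assert regs[0].peak_stat == 3.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 10**6), st.integers(1, 5000)),
                    min_size=1, max_size=30))
    def test_merging_is_idempotent(self, spans):
        wins = [win("s", a, a + w - 1) for a, w in spans]
        regs = merge_regions(wins)
        rewins = [win(r.scaffold, r.start, r.end) for r in regs]
        again = merge_regions(rewins)
        assert [(r.start, r.end) for r in again] \
            == [(r.start, r.end) for r in regs]
        assert len(regs) <= len(wins)


class TestAnnotateGenes:
    @pytest.mark.parametrize(
        "gene_start, attached",
        [
            (25000, True),   # 19999 intervening bases
            (25001, False),  # 20000: gene no longer intersects the +20kb flank
            (25002, False),  # 20001
            (3000, True),    # inside the region
        ],
    )
    def test_flank_boundary(self, gene_start, attached):
        regs = [region("s", 1000, 5000)]
        genes = [GeneModel("s", gene_start, gene_start + 1000, "+", "g1")]
        out = annotate_genes(regs, genes, flank=20000)
        assert (len(out[0].genes) == 1) is attached

    def test_upstream_flank_boundary(self):
        regs = [region("s", 50000, 55000)]
        g_in = GeneModel("s", 29000, 30000, "+", "gin")  # end at flank edge
        g_out = GeneModel("s", 29000, 29999, "+", "gout")
        out = annotate_genes(regs, [g_in, g_out], flank=20000)
        assert [g.gene_id for g in out[0].genes] == ["gin"]

    def test_other_scaffold_never_attached(self):
        out = annotate_genes([region("s1", 1000, 5000)],
                             [GeneModel("s2", 1000, 5000, "+", "g")])
        assert out[0].genes == []


class TestSharedRegions:
    def test_formula_instantiation(self):
        # 5 of 10 A-regions intersect B; 5 of 20 B-regions intersect A
        a = [region("s", i * 100_000, i * 100_000 + 100) for i in range(10)]
        b = [region("s", i * 100_000 + 50, i * 100_000 + 80) for i in range(5)]
        b += [region("other", i * 100_000, i * 100_000 + 100) for i in range(15)]
        rep = shared_regions(a, b)
        assert rep.pct_shared_regions == pytest.approx(
            100 * 0.5 * (5 / 10 + 5 / 20))

    def test_identical_sets_give_100(self):
        a = [region("s", 1, 100), region("s", 1000, 1100)]
        assert shared_regions(a, a).pct_shared_regions == 100.0

    def test_disjoint_sets_give_0(self):
        a = [region("s", 1, 100)]
        b = [region("s", 500, 600)]
        assert shared_regions(a, b).pct_shared_regions == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        a = [region("s", int(x), int(x) + 500) for x in
             rng.integers(1, 10**6, 12)]
        b = [region("s", int(x), int(x) + 500) for x in
             rng.integers(1, 10**6, 7)]
        assert shared_regions(a, b).pct_shared_regions \
            == pytest.approx(shared_regions(b, a).pct_shared_regions)

    def test_empty_set_warns_and_gives_0(self):
        with pytest.warns(UserWarning, match="empty"):
            rep = shared_regions([], [region("s", 1, 10)])
        assert rep.pct_shared_regions == 0.0


class TestSharedAcross:
    def test_common_locus_found(self):
        sets = [
            [region("s", 100, 200)],
            [region("s", 150, 400)],
            [region("s", 180, 210)],
        ]
        loci = shared_across(sets)
        assert [(l.scaffold, l.start, l.end) for l in loci] == [("s", 180, 200)]

    def test_any_empty_set_gives_empty_result(self):
        assert shared_across([[region("s", 1, 10)], []]) == []

    def test_result_within_every_pairwise_intersection(self):
        rng = np.random.default_rng(4)
        sets = []
        for _ in range(3):
            sets.append([region("s", int(x), int(x) + 2000)
                         for x in sorted(rng.integers(1, 50_000, 6))])
        loci = shared_across(sets)
        for i in range(3):
            for j in range(i + 1, 3):
                pairwise = shared_across([sets[i], sets[j]])
                for locus in loci:
                    assert any(p.scaffold == locus.scaffold
                               and p.start <= locus.start
                               and locus.end <= p.end for p in pairwise)


class TestSharedPolymorphism:
    def test_formula_instantiation(self):
        a = {("s", i) for i in range(100)}
        b = {("s", i) for i in range(50, 250)}
        assert shared_polymorphism(a, b) == pytest.approx(
            100 * 0.5 * (50 / 100 + 50 / 200))

    def test_identical_sets_give_100(self):
        a = {("s", 1), ("s", 2)}
        assert shared_polymorphism(a, set(a)) == 100.0

    def test_disjoint_sets_give_0(self):
        assert shared_polymorphism({("s", 1)}, {("s", 2)}) == 0.0

    def test_symmetric(self):
        a = {("s", i) for i in range(30)}
        b = {("s", i) for i in range(20, 40)}
        assert shared_polymorphism(a, b) == shared_polymorphism(b, a)

    def test_empty_set_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            shared_polymorphism(set(), {("s", 1)})
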