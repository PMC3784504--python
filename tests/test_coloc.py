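"""Locus-set algebra, the shuffled-placement null, and profile correlation."""

import numpy as np
import pytest
from scipy import stats as sps

from chiptile import (
    IntervalRecord,
    LocusSet,
    overlap_count,
    overlap_enrichment,
    shared_loci,
    shuffle_intervals,
    track_correlation,
    venn_counts,
)
from chiptile.errors import ConfigurationError, GridMismatchError

from ._oracles import (
    overlap_count_oracle,
    pearson_oracle,
    single_interval_overlap_given_b,
)
from .conftest import make_track

GENOME = {"chr1": 100_000, "chr2": 80_000}


def loci(name, intervals, genome=GENOME, **kwargs):
    return LocusSet(name, intervals, genome, **kwargs)


class TestLocusSet:
    def test_overlapping_intervals_merge_on_construction(self):
        s = loci("a", [("chr1", 100, 600), ("chr1", 400, 900), ("chr1", 900, 950)])
        assert s.intervals == (("chr1", 100, 900, 0.0), ("chr1", 900, 950, 0.0))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            loci("a", [("chr1", 99_990, 100_010)])
        with pytest.raises(ConfigurationError):
            loci("a", [("chrX", 0, 10)])

    def test_records_carry_the_set_name(self):
        s = loci("nap1", [("chr1", 0, 10)])
        assert s.records == [IntervalRecord("chr1", 0, 10, "nap1", 0.0)]


class TestSharedLoci:
    def test_disjoint_sets_share_nothing(self):
        a = loci("a", [("chr1", 0, 100)])
        b = loci("b", [("chr1", 200, 300)])
        assert len(shared_loci(a, b)) == 0

    def test_idempotence(self):
        a = loci("a", [("chr1", 100, 600), ("chr2", 0, 50)])
        shared = shared_loci(a, a)
        assert shared.intervals == tuple(
            (c, s, e, v) for c, s, e, v in a.intervals
        )

    def test_interval_arithmetic(self):
        a = loci("a", [("chr1", 100, 600)])
        b = loci("b", [("chr1", 400, 900)])
        assert [(r.chrom, r.start, r.end) for r in shared_loci(a, b).records] == [
            ("chr1", 400, 600)
        ]

    def test_symmetric_regions(self):
        rng = np.random.default_rng(1)
        a = loci("a", [("chr1", int(s), int(s) + 500) for s in rng.integers(0, 99_000, 30)])
        b = loci("b", [("chr1", int(s), int(s) + 300) for s in rng.integers(0, 99_000, 30)])
        ab = {(c, s, e) for c, s, e, _ in shared_loci(a, b).intervals}
        ba = {(c, s, e) for c, s, e, _ in shared_loci(b, a).intervals}
        assert ab == ba

    def test_genome_mismatch_rejected(self):
        a = loci("a", [("chr1", 0, 10)])
        b = LocusSet("b", [("chr1", 0, 10)], {"chr1": 50_000})
        with pytest.raises(ConfigurationError):
            shared_loci(a, b)


class TestOverlapCount:
    def test_empty_b_gives_zero(self):
        a = loci("a", [("chr1", 0, 100)])
        assert overlap_count(a, loci("b", [])) == 0

    def test_self_overlap_counts_every_locus(self):
        a = loci("a", [("chr1", 0, 100), ("chr1", 200, 300), ("chr2", 0, 10)])
        assert overlap_count(a, a) == 3

    def test_small_example_against_brute_force(self):
        a = loci("a", [("chr1", 0, 100), ("chr1", 500, 700), ("chr2", 0, 50)])
        b = loci("b", [("chr1", 50, 120), ("chr2", 40, 90)])
        expected = overlap_count_oracle(
            [(c, s, e) for c, s, e, _ in a.intervals],
            [(c, s, e) for c, s, e, _ in b.intervals],
        )
        assert overlap_count(a, b) == expected == 2

    def test_random_sets_match_quadratic_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a_iv = [
                ("chr1", int(s), int(s + rng.integers(1, 800)))
                for s in rng.integers(0, 90_000, 25)
            ]
            b_iv = [
                ("chr2" if rng.random() < 0.3 else "chr1", int(s), int(s + rng.integers(1, 500)))
                for s in rng.integers(0, 70_000, 25)
            ]
            a = loci("a", a_iv)
            b = loci("b", b_iv)
            expected = overlap_count_oracle(
                [(c, s, e) for c, s, e, _ in a.intervals],
                [(c, s, e) for c, s, e, _ in b.intervals],
            )
            assert overlap_count(a, b) == expected


class TestShuffle:
    def test_length_multiset_preserved(self):
        rng = np.random.default_rng(2)
        a = loci("a", [("chr1", int(s), int(s) + int(w)) for s, w in
                       zip(rng.integers(0, 90_000, 40), rng.integers(50, 900, 40))])
        shuffled = shuffle_intervals(a, 3)
        assert sorted(shuffled.lengths()) == sorted(a.lengths())

    def test_forced_placement_when_chromosome_equals_length(self):
        a = LocusSet("a", [("chr1", 0, 100)], {"chr1": 100})
        shuffled = shuffle_intervals(a, 4)
        assert shuffled.intervals[0][:3] == ("chr1", 0, 100)

    def test_locus_longer_than_chromosome_rejected(self):
        # construction already enforces bounds ...
        with pytest.raises(ConfigurationError):
            LocusSet("c", [("chr1", 0, 200)], {"chr1": 100})
        # ... and shuffling re-checks them against a corrupted reference
        a = LocusSet("a", [("chr1", 0, 100)], {"chr1": 100})
        a.genome["chr1"] = 50
        with pytest.raises(ConfigurationError):
            shuffle_intervals(a, 1)

    def test_start_positions_uniform(self):
        """Single 10 bp locus on a 100 bp chromosome: starts are uniform on
        {0..90} (chi-square goodness of fit at the 1% level, 10,000 draws)."""
        a = LocusSet("a", [("chr1", 20, 30)], {"chr1": 100})
        rng = np.random.default_rng(5)
        starts = [shuffle_intervals(a, rng).intervals[0][1] for _ in range(10_000)]
        observed = np.bincount(starts, minlength=91)
        assert observed.size == 91
        statistic, p = sps.chisquare(observed)
        assert p > 0.01

    def test_shuffled_loci_may_overlap_each_other(self):
        a = LocusSet("a", [("chr1", 0, 400), ("chr1", 500, 900)], {"chr1": 1000})
        rng = np.random.default_rng(0)
        saw_overlap = False
        for _ in range(200):
            s = shuffle_intervals(a, rng)
            (c1, s1, e1, _), (c2, s2, e2, _) = s.intervals
            if s1 < e2 and s2 < e1:
                saw_overlap = True
                break
        assert saw_overlap
        assert len(s) == 2  # not merged


class TestOverlapEnrichment:
    def test_saturated_genome_gives_fold_near_one(self):
        # b tiles the genome densely: any placement of a overlaps something
        b = loci("b", [("chr1", s, s + 900) for s in range(0, 99_000, 1000)])
        a = loci("a", [("chr1", s, s + 500) for s in range(100, 50_000, 2500)])
        stats = overlap_enrichment(a, b, n_shuffles=200, rng=1)
        assert stats.observed == len(a)
        assert 0.9 < stats.fold < 1.1

    def test_single_interval_null_matches_conditional_enumeration(self):
        """B fixed mid-chromosome, A re-placed uniformly: the Monte-Carlo
        null mean must match exact enumeration of all 91 A placements."""
        genome = {"chr1": 100}
        a = LocusSet("a", [("chr1", 0, 10)], genome)
        b = LocusSet("b", [("chr1", 45, 55)], genome)
        n = 10_000
        stats = overlap_enrichment(a, b, n_shuffles=n, rng=7)
        exact = single_interval_overlap_given_b(100, 10, 45, 10)
        mc_se = np.sqrt(exact * (1 - exact) / n)
        assert abs(stats.null_mean - exact) < 3 * mc_se

    def test_p_value_floor(self):
        genome = {"chr1": 100_000}
        intervals = [("chr1", s, s + 10) for s in range(0, 20_000, 1000)]
        a = LocusSet("a", intervals, genome)
        stats = overlap_enrichment(a, a, n_shuffles=999, rng=9)
        assert stats.p_value >= 1 / 1000
        assert stats.p_value == 1 / 1000  # self-overlap beats every shuffle

    def test_fold_infinite_when_null_never_overlaps(self):
        genome = {"chr1": 1_000_000, "chr2": 1_000_000}
        a = LocusSet("a", [("chr1", 0, 10)], genome)
        b = LocusSet("b", [("chr2", 0, 10)], genome)  # different chromosome
        stats = overlap_enrichment(a, b, n_shuffles=50, rng=2)
        assert stats.observed == 0
        assert stats.null_mean == 0
        assert np.isinf(stats.fold)


class TestVenn:
    def test_disjoint_sets_have_empty_intersections(self):
        a = loci("a", [("chr1", 0, 100)])
        b = loci("b", [("chr1", 200, 300)])
        counts = venn_counts([a, b])
        assert counts.counts["a"] == {("a",): 1}
        assert counts.counts["b"] == {("b",): 1}

    def test_identical_triple_sets(self):
        intervals = [("chr1", s, s + 100) for s in range(0, 5000, 500)]
        a, b, c = (loci(n, intervals) for n in "abc")
        counts = venn_counts([a, b, c])
        for name in "abc":
            assert counts.counts[name] == {("a", "b", "c"): 10}
            assert counts.total(name) == 10

    def test_hand_built_sets_match_brute_force(self):
        a = loci("a", [("chr1", 0, 100), ("chr1", 1000, 1100), ("chr2", 0, 60)])
        b = loci("b", [("chr1", 50, 160), ("chr2", 1000, 1100)])
        c = loci("c", [("chr1", 90, 95), ("chr1", 1050, 1060)])
        counts = venn_counts([a, b, c])

        def membership(owner, interval, others):
            got = {owner.name}
            for other in others:
                if overlap_count_oracle(
                    [interval], [(x, s, e) for x, s, e, _ in other.intervals]
                ):
                    got.add(other.name)
            return tuple(sorted(got))

        for owner in (a, b, c):
            others = [s for s in (a, b, c) if s is not owner]
            expected: dict = {}
            for c_, s_, e_, _ in owner.intervals:
                key = membership(owner, (c_, s_, e_), others)
                expected[key] = expected.get(key, 0) + 1
            assert counts.counts[owner.name] == expected

    def test_per_set_counts_sum_to_set_size(self):
        rng = np.random.default_rng(3)
        sets = [
            loci(
                name,
                [("chr1", int(s), int(s) + 400) for s in rng.integers(0, 99_000, 20)],
            )
            for name in ("x", "y", "z")
        ]
        counts = venn_counts(sets)
        for s in sets:
            assert counts.total(s.name) == len(s)

    def test_more_than_three_sets_unsupported(self):
        sets = [loci(str(i), [("chr1", 0, 10)]) for i in range(4)]
        with pytest.raises(ConfigurationError):
            venn_counts(sets)


class TestTrackCorrelation:
    def test_identical_tracks_give_one(self):
        x = make_track([1.0, 2.0, 3.0, 4.0])
        assert track_correlation(x, x) == pytest.approx(1.0)

    def test_negated_track_gives_minus_one(self):
        x = make_track([1.0, 2.0, 3.0, 4.0])
        y = make_track([-1.0, -2.0, -3.0, -4.0])
        assert track_correlation(x, y) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = make_track([1.0, 2.0, 3.0, 4.0])
        y = make_track([2.0, 4.0, 5.0, 4.0])
        expected = pearson_oracle([1, 2, 3, 4], [2, 4, 5, 4])
        assert track_correlation(x, y) == pytest.approx(expected)
        assert expected == pytest.approx(3.5 / np.sqrt(5.0 * 4.75))

    def test_zero_variance_is_signalled(self):
        x = make_track([1.0, 1.0, 1.0])
        y = make_track([1.0, 2.0, 3.0])
        with pytest.raises(ConfigurationError):
            track_correlation(x, y)

    def test_grid_mismatch_rejected(self):
        x = make_track([1.0, 2.0])
        y = make_track([1.0, 2.0], chrom="chr2")
        with pytest.raises(GridMismatchError):
            track_correlation(x, y)
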