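import numpy as np
import pandas as pd
import pytest

from islandkit.core import GenomicInterval
from islandkit.enrichment import (
    DensityTrack,
    EnrichedWindow,
    NullModel,
    ReadSet,
    build_density,
    build_null,
    call_enriched_windows,
    classify_promoters,
    coverage_cumsum,
    gc_matrix,
    merge_regions,
    signal_matrix,
    spreading_extent,
    window_pvalue,
    window_values,
    EnrichedRegion,
)
from islandkit.simulate import ChipSpec, EnrichedSpec, generate_reads


def make_readset(tuples, ext=200):
    return ReadSet.from_tuples(tuples, extension_bp=ext)


class TestBuildDensity:
    def test_plus_read_hand_layout(self):
        rs = make_readset([("c", 0, "+")])
        track = build_density(rs, {"c": 1000}, bin_bp=25)["c"]
        # extension [0, 200) covers bins 0..7 exactly
        assert track.counts[:8].tolist() == [1] * 8
        assert track.counts[8:].sum() == 0

    def test_minus_read_hand_layout(self):
        rs = make_readset([("c", 1000, "-")])
        track = build_density(rs, {"c": 2000}, bin_bp=25)["c"]
        # extension [800, 1000) covers bins 32..39
        covered = np.flatnonzero(track.counts)
        assert covered.tolist() == list(range(32, 40))

    def test_empty_readset_all_zero(self):
        rs = ReadSet(reads={})
        track = build_density(rs, {"c": 1000})["c"]
        assert track.counts.sum() == 0

    def test_read_beyond_end_clipped_and_counted(self):
        rs = make_readset([("c", 950, "+")])
        tracks = build_density(rs, {"c": 1000}, bin_bp=25)
        assert tracks["c"].clipped_reads == 1
        assert tracks["c"].counts[38:40].tolist() == [1, 1]

    def test_aligned_reads_bin_count_invariant(self):
        # aligned reads cover exactly ceil(extension/bin) bins each
        rs = make_readset([("c", 0, "+"), ("c", 500, "+"), ("c", 200, "+")])
        track = build_density(rs, {"c": 2000}, bin_bp=25)["c"]
        assert track.counts.sum() == 3 * (200 // 25)


class TestCoverageStatistic:
    def test_window_value_equals_overlap_sum(self):
        rs = make_readset([("c", 100, "+"), ("c", 950, "+"), ("c", 1500, "-")])
        cs = coverage_cumsum(rs, "c", 3000)
        vals = window_values(cs, np.array([0]), 1000, 200)
        # read1 fully inside (200bp), read2 overlaps [950,1000)=50bp,
        # read3 extends [1300,1500), outside
        assert vals[0] == pytest.approx((200 + 50) / 200)


class TestBuildNull:
    def test_mean_matches_poisson_expectation(self):
        spec = ChipSpec(contig="c", background_per_kb=10.0)
        rs, _ = generate_reads(spec, {"c": 1_000_000}, seed=5)
        null = build_null(rs, {"c": 1_000_000}, window_bp=1000, n_rand=10, seed=1)
        expected = rs.total_count * 1000 / 1_000_000
        assert null.mean == pytest.approx(expected, rel=0.05)

    def test_seeded_determinism(self):
        spec = ChipSpec(contig="c", background_per_kb=5.0)
        rs, _ = generate_reads(spec, {"c": 200_000}, seed=5)
        a = build_null(rs, {"c": 200_000}, seed=42)
        b = build_null(rs, {"c": 200_000}, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_more_randomizations_converge(self):
        spec = ChipSpec(contig="c", background_per_kb=5.0)
        rs, _ = generate_reads(spec, {"c": 500_000}, seed=5)

        def tv_distance(n_rand, seed):
            null = build_null(rs, {"c": 500_000}, n_rand=n_rand, seed=seed)
            other = build_null(rs, {"c": 500_000}, n_rand=n_rand, seed=seed + 100)
            grid = np.linspace(0, 15, 60)
            cdf_a = np.searchsorted(null.values, grid) / null.n_samples
            cdf_b = np.searchsorted(other.values, grid) / other.n_samples
            return np.abs(cdf_a - cdf_b).max()

        small = np.mean([tv_distance(2, s) for s in range(3)])
        large = np.mean([tv_distance(16, s) for s in range(3)])
        assert large < small

    def test_n_rand_validation(self):
        rs = make_readset([("c", 0, "+")])
        with pytest.raises(ValueError):
            build_null(rs, {"c": 1000}, n_rand=0)


class TestWindowPvalue:
    def toy_null(self, values):
        return NullModel(
            window_bp=1000, n_randomizations=1, seed=0,
            total_count=100, values=np.asarray(values, dtype=float),
        )

    def test_count_zero_p_one(self):
        null = self.toy_null(np.arange(50))
        assert window_pvalue(0, null) == pytest.approx(1.0)

    def test_above_max_tail_floor(self):
        null = self.toy_null(np.arange(50))
        assert window_pvalue(1000, null) == pytest.approx(1 / 51)

    def test_hand_tally_50_windows(self):
        values = np.arange(50)  # 0..49
        null = self.toy_null(values)
        # count=30: null windows >= 30 are 30..49 -> 20 of them
        assert window_pvalue(30, null) == pytest.approx((20 + 1) / 51)
        # count=49.5: only values above -> 0 plus smoothing
        assert window_pvalue(49.5, null) == pytest.approx(1 / 51)

    def test_monotone_in_count(self):
        null = self.toy_null(np.sort(np.random.default_rng(0).random(100)))
        ps = [window_pvalue(c, null) for c in np.linspace(0, 1.2, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            window_pvalue(-1, self.toy_null(np.arange(5)))


class TestCallEnrichedWindows:
    def test_empty_readset(self):
        rs = ReadSet(reads={})
        assert call_enriched_windows(rs, {"c": 100_000}, seed=1) == []

    def test_planted_region_called(self):
        spec = ChipSpec(
            contig="c", background_per_kb=5.0,
            enriched=(EnrichedSpec(100_000, 102_000, 8.0),),
        )
        rs, _ = generate_reads(spec, {"c": 300_000}, seed=9)
        wins = call_enriched_windows(rs, {"c": 300_000}, seed=10)
        plant = GenomicInterval("c", 100_000, 102_000)
        assert any(w.interval.overlaps(plant) for w in wins)

    def test_type_one_error_modest_fixture(self):
        # pure-null reads: called fraction should be near the threshold
        spec = ChipSpec(contig="c", background_per_kb=10.0)
        rs, _ = generate_reads(spec, {"c": 1_000_000}, seed=3)
        wins = call_enriched_windows(
            rs, {"c": 1_000_000}, step_bp=500, p_threshold=1e-2, seed=4
        )
        n_windows = len(np.arange(0, 1_000_000 - 1000 + 1, 500))
        frac = len(wins) / n_windows
        assert frac < 0.05  # loose sanity bound; calibration tested in acceptance


class TestMergeRegions:
    def win(self, start, end, value=10.0, p=1e-4, contig="c"):
        return EnrichedWindow(GenomicInterval(contig, start, end), value, p)

    def test_gap_800_merges(self):
        regions = merge_regions([self.win(0, 1000), self.win(1800, 2800)], gap_bp=1000)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 2800)
        assert regions[0].width_bp == 2800

    def test_gap_1500_does_not_merge(self):
        regions = merge_regions([self.win(0, 1000), self.win(2500, 3500)], gap_bp=1000)
        assert len(regions) == 2

    def test_transitive_chain(self):
        wins = [self.win(i * 1900, i * 1900 + 1000) for i in range(5)]  # gaps of 900
        regions = merge_regions(wins, gap_bp=1000)
        assert len(regions) == 1
        assert regions[0].interval.end - regions[0].interval.start == 4 * 1900 + 1000

    def test_region_p_is_min_member_p(self):
        wins = [self.win(0, 1000, p=1e-4), self.win(500, 1500, p=1e-6)]
        assert merge_regions(wins)[0].p_value == 1e-6

    def test_invariant_to_input_order(self, rng):
        wins = [
            self.win(int(s), int(s) + 1000, value=float(rng.random()))
            for s in rng.integers(0, 50_000, size=30)
        ]
        a = merge_regions(wins)
        b = merge_regions(list(reversed(wins)))
        assert a == b

    def test_idempotent(self):
        wins = [self.win(0, 1000), self.win(1800, 2800), self.win(9000, 10_000)]
        regions = merge_regions(wins)
        as_windows = [
            EnrichedWindow(r.interval, 1.0, r.p_value) for r in regions
        ]
        again = merge_regions(as_windows)
        assert [r.interval for r in again] == [r.interval for r in regions]

    def test_output_disjoint_with_gaps_above_threshold(self, rng):
        wins = [
            self.win(int(s), int(s) + 1000)
            for s in rng.integers(0, 100_000, size=60)
        ]
        regions = merge_regions(wins, gap_bp=1000)
        for a, b in zip(regions, regions[1:]):
            assert b.interval.start - a.interval.end > 1000

    def test_empty(self):
        assert merge_regions([]) == []


class TestClassifyPromoters:
    def planted_cohort(self, seed=21):
        L = 400_000
        promoters = [("p_k4", "c", 50_000), ("p_biv", "c", 150_000),
                     ("p_none", "c", 250_000)]
        k4_spec = ChipSpec(
            contig="c", background_per_kb=5.0,
            enriched=(
                EnrichedSpec(49_000, 51_000, 10.0),
                EnrichedSpec(149_000, 151_000, 10.0),
            ),
        )
        k27_spec = ChipSpec(
            contig="c", background_per_kb=5.0,
            enriched=(EnrichedSpec(149_000, 151_000, 10.0),),
        )
        k4, _ = generate_reads(k4_spec, {"c": L}, seed=seed)
        k27, _ = generate_reads(k27_spec, {"c": L}, seed=seed + 1)
        return promoters, {"K4me3": k4, "K27me3": k27}, {"c": L}

    def test_planted_states(self):
        promoters, readsets, lengths = self.planted_cohort()
        table, overlap = classify_promoters(
            promoters, readsets, lengths, seed=33
        )
        t = table.set_index("id")
        assert bool(t.loc["p_k4", "K4me3"]) and not bool(t.loc["p_k4", "K27me3"])
        assert bool(t.loc["p_biv", "bivalent"])
        assert not bool(t.loc["p_none", "K4me3"])
        assert not bool(t.loc["p_none", "K27me3"])
        assert overlap.get(("K4me3",)) == 1
        assert overlap.get(("K27me3", "K4me3")) == 1
        assert overlap.get(()) == 1

    def test_no_reads_all_negative(self):
        promoters = [("p1", "c", 5000), ("p2", "c", 8000)]
        empty = ReadSet(reads={})
        table, _ = classify_promoters(
            promoters, {"K4me3": empty}, {"c": 20_000}, seed=1
        )
        assert not table["K4me3"].any()

    def test_identical_readsets_identical_columns(self):
        promoters, readsets, lengths = self.planted_cohort()
        same = {"A": readsets["K4me3"], "B": readsets["K4me3"]}
        table, _ = classify_promoters(promoters, same, lengths, seed=7)
        assert (table["A"] == table["B"]).all()


class TestSignalMatrix:
    def make_setup(self):
        counts = np.zeros(4000, dtype=np.int64)  # 100 kb at 25 bp bins
        density = {"c": DensityTrack("c", 25, counts)}
        regions = [
            EnrichedRegion(GenomicInterval("c", 10_000, 15_000), 1e-5, 12_500),
            EnrichedRegion(GenomicInterval("c", 40_000, 42_000), 1e-5, 41_000),
            EnrichedRegion(GenomicInterval("c", 70_000, 71_000), 1e-5, 70_500),
        ]
        islands = [
            GenomicInterval("c", 12_000, 12_500),
            GenomicInterval("c", 70_200, 70_700),
        ]
        return regions, density, islands

    def test_groups_and_width_order(self):
        regions, density, islands = self.make_setup()
        matrix, meta = signal_matrix(regions, density, islands, span_bp=20_000)
        assert matrix.shape == (3, 800)
        # group 0 (island overlap): widths 5000 then 1000; group 1: the 2 kb one
        assert meta["group"].tolist() == [0, 0, 1]
        assert meta["width_bp"].tolist() == [5000, 1000, 2000]

    def test_tie_order_by_coordinate(self):
        counts = np.zeros(4000, dtype=np.int64)
        density = {"c": DensityTrack("c", 25, counts)}
        regions = [
            EnrichedRegion(GenomicInterval("c", 50_000, 51_000), 1e-5, 50_500),
            EnrichedRegion(GenomicInterval("c", 20_000, 21_000), 1e-5, 20_500),
        ]
        _, meta = signal_matrix(regions, density, [], span_bp=10_000)
        assert meta["start"].tolist() == [20_000, 50_000]

    def test_center_column_alignment(self):
        counts = np.zeros(4000, dtype=np.int64)
        counts[41_000 // 25] = 7  # spike at one region's midpoint
        density = {"c": DensityTrack("c", 25, counts)}
        regions = [EnrichedRegion(GenomicInterval("c", 40_000, 42_000), 1e-5, 41_000)]
        matrix, _ = signal_matrix(regions, density, [], span_bp=20_000)
        assert matrix[0, matrix.shape[1] // 2] == 7

    def test_edge_rows_nan_padded(self):
        counts = np.zeros(400, dtype=np.int64)  # 10 kb contig
        density = {"c": DensityTrack("c", 25, counts)}
        regions = [EnrichedRegion(GenomicInterval("c", 1000, 2000), 1e-5, 1500)]
        matrix, _ = signal_matrix(regions, density, [], span_bp=20_000)
        assert np.isnan(matrix[0, 0])
        assert not np.isnan(matrix[0, matrix.shape[1] // 2])

    def test_empty(self):
        matrix, meta = signal_matrix([], {}, [])
        assert matrix.size == 0 and meta.empty


class TestGcMatrix:
    def test_values_match_sequence(self):
        from islandkit.core import GenomeSequence

        g = GenomeSequence({"c": "G" * 5000 + "A" * 5000})
        meta = pd.DataFrame([{"contig": "c", "start": 4000, "end": 6000}])
        m = gc_matrix(g, meta, span_bp=2000, bin_bp=100)
        # row centred at 5000: first half G (gc=1), second half A (gc=0)
        assert m[0, 0] == pytest.approx(1.0)
        assert m[0, -1] == pytest.approx(0.0)


class TestSpreadingExtent:
    def test_reported_geometry(self):
        # amplicons at 0.5/1.5/2.5/3.5 kb, enrichment 8/5/3/1, threshold 2
        extent = spreading_extent([500, 1500, 2500, 3500], [8, 5, 3, 1], threshold=2)
        assert extent == 2500

    def test_all_below_threshold(self):
        assert spreading_extent([500, 1500], [1, 1], threshold=2) == 0

    def test_monotone_in_threshold(self):
        pos = [500, 1500, 2500, 3500]
        val = [8, 5, 3, 1]
        extents = [spreading_extent(pos, val, threshold=t) for t in (1, 2, 4, 6, 9)]
        assert all(a >= b for a, b in zip(extents, extents[1:]))

    def test_contiguity_stops_scan(self):
        # a later supra-threshold point does not extend past the first gap
        extent = spreading_extent([500, 1500, 2500], [8, 1, 9], threshold=2)
        assert extent == 500

    def test_with_insert_interval_both_sides(self):
        insert = GenomicInterval("c", 10_000, 12_000)
        pos = [9_500, 8_500, 12_499, 13_499, 14_499]
        val = [5, 1, 7, 4, 1]
        # left: 500 ok, 1500 below -> 500; right: 500, 1500 ok, 2500 below -> 1500
        assert spreading_extent(pos, val, insert=insert, threshold=2) == 1500
        assert spreading_extent(pos, val, insert=insert, threshold=2, side="left") == 500


class TestReadSetBasics:
    def test_total_count(self):
        rs = make_readset([("c", 1, "+"), ("c", 2, "-"), ("d", 3, "+")])
        assert rs.total_count == 3

    def test_tuples_round_trip(self):
        tuples = [("c", 5, "+"), ("c", 1, "-"), ("d", 7, "+")]
        rs = make_readset(tuples)
        assert sorted(rs.to_tuples()) == sorted(tuples)

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError):
            ReadSet(reads={"c": (np.array([1]), np.array([2], dtype=np.int8))})
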