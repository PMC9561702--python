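"""BSA mapping: frequency tracks, smoothing, peak calling, introgression
detection and fine mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forgen import bsa, simulate
from forgen.simulate import CausalLocus, CrossSpec

from conftest import manual_map


def make_counts(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "ref_reads", "alt_reads", "base_quality"])


def make_track(freqs, chrom="chr1", spacing=1000):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": np.arange(1, len(freqs) + 1) * spacing,
            "freq": freqs,
            "depth": 50,
            "passed_filters": True,
        }
    )


class TestMutantAlleleFrequency:
    def test_fixed_site(self):
        track = bsa.mutant_allele_frequency(make_counts([("chr1", 100, 0, 30, 150.0)]))
        assert track["freq"].iloc[0] == 1.0
        assert bool(track["passed_filters"].iloc[0])

    def test_depth_filter(self):
        track = bsa.mutant_allele_frequency(make_counts([("chr1", 100, 14, 15, 150.0)]))
        assert not track["passed_filters"].iloc[0]
        assert np.isnan(track["freq"].iloc[0])

    def test_quality_filter(self):
        track = bsa.mutant_allele_frequency(make_counts([("chr1", 100, 10, 30, 99.0)]))
        assert not track["passed_filters"].iloc[0]

    def test_hand_computed_fraction(self):
        track = bsa.mutant_allele_frequency(make_counts([("chr1", 100, 9, 27, 150.0)]))
        assert track["freq"].iloc[0] == pytest.approx(0.75)

    def test_empty_input(self):
        assert bsa.mutant_allele_frequency(make_counts([])).empty


class TestRollingAverage:
    def test_constant_track_unchanged(self):
        sm = bsa.rolling_average(make_track([0.5] * 10), 3, "markers")
        assert np.allclose(sm["smoothed_freq"], 0.5)

    def test_three_marker_mean(self):
        sm = bsa.rolling_average(make_track([0.4, 0.6, 0.8]), 3, "markers")
        assert sm["smoothed_freq"].iloc[1] == pytest.approx(0.6)

    def test_singleton_window_is_identity(self):
        freqs = [0.2, 0.9, 0.4]
        sm = bsa.rolling_average(make_track(freqs, spacing=10_000), 100, "bp")
        assert np.allclose(sm["smoothed_freq"], freqs)

    def test_invalid_units(self):
        with pytest.raises(ValueError):
            bsa.rolling_average(make_track([0.5]), 3, "furlongs")

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40))
    @settings(max_examples=50, derandomize=True)
    def test_smoothing_stays_in_convex_hull(self, freqs):
        sm = bsa.rolling_average(make_track(freqs), 5, "markers")
        vals = sm["smoothed_freq"].to_numpy()
        assert np.nanmin(vals) >= min(freqs) - 1e-12
        assert np.nanmax(vals) <= max(freqs) + 1e-12

    def test_failed_sites_excluded(self):
        track = make_track([0.1, 0.9, 0.1])
        track.loc[1, "passed_filters"] = False
        track.loc[1, "freq"] = np.nan
        sm = bsa.rolling_average(track, 3, "markers")
        assert np.isnan(sm["smoothed_freq"].iloc[1])
        assert sm["smoothed_freq"].iloc[0] == pytest.approx(0.1)


class TestCallCandidateRegion:
    def test_all_below_threshold(self):
        sm = bsa.rolling_average(make_track([0.5] * 20), 3, "markers")
        assert bsa.call_candidate_region(sm).empty

    def test_all_fixed_single_interval_peak_first(self):
        sm = bsa.rolling_average(make_track([1.0] * 20), 3, "markers")
        intervals = bsa.call_candidate_region(sm)
        assert len(intervals) == 1
        row = intervals.iloc[0]
        assert row["start_bp"] == 1000 and row["end_bp"] == 20_000
        assert row["peak_bp"] == 1000  # leftmost tie-break

    def test_min_sites_enforced(self):
        sm = bsa.rolling_average(make_track([0.95] * 3 + [0.5] * 10), 1, "markers")
        assert bsa.call_candidate_region(sm, min_sites=5).empty

    def test_simulated_bulk_localises_causal_locus(self):
        mmap = simulate.build_marker_map(1, 100, 100_000_000, 1.0, seed=21)
        _pop, _bulk, counts = simulate.simulate_bsa_experiment(
            mmap, CausalLocus("chr1", 50_000_000), n_f2=200, bulk_size=50,
            mean_depth=40, error_rate=0.01, seed=22,
        )
        track = bsa.mutant_allele_frequency(counts)
        sm = bsa.rolling_average(track, 5, "markers")
        intervals = bsa.call_candidate_region(sm, 0.9, 5)
        assert len(intervals) == 1
        assert intervals["start_bp"].iloc[0] <= 50_000_000 <= intervals["end_bp"].iloc[0]


class TestChipBsaClassify:
    @pytest.mark.parametrize(
        "freq,expected",
        [(0.50, "heterozygous"), (0.98, "homozygous_mutant"), (0.75, "intermediate")],
    )
    def test_band_classification(self, freq, expected):
        assert bsa.chip_bsa_classify([freq])[0] == expected

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bsa.chip_bsa_classify([1.2])


class TestDetectIntrogressions:
    @pytest.fixture()
    def parents(self, two_chrom_map):
        rec = two_chrom_map.markers["allele_A"].to_numpy()
        don = two_chrom_map.markers["allele_B"].to_numpy()
        return rec, don

    def test_pure_recurrent_gives_nothing(self, two_chrom_map, parents):
        rec, don = parents
        segs = bsa.detect_introgressions(rec.copy(), rec, don, two_chrom_map)
        assert segs.empty

    def test_round_trip_recovers_segment_bounds(self, two_chrom_map, parents):
        rec, don = parents
        sub = two_chrom_map.markers[two_chrom_map.markers["chrom"] == "chr1"]
        start, end = int(sub["pos_bp"].iloc[39]), int(sub["pos_bp"].iloc[49])
        nil = simulate.simulate_nil(two_chrom_map, [("chr1", start, end)], rec, don)
        segs = bsa.detect_introgressions(nil, rec, don, two_chrom_map)
        assert len(segs) == 1
        assert segs["start_bp"].iloc[0] == start
        assert segs["end_bp"].iloc[0] == end

    def test_gap_rule_splits_separated_blocks(self, two_chrom_map, parents):
        rec, don = parents
        sub = two_chrom_map.markers[two_chrom_map.markers["chrom"] == "chr1"]
        seg_a = ("chr1", int(sub["pos_bp"].iloc[0]), int(sub["pos_bp"].iloc[4]))
        seg_b = ("chr1", int(sub["pos_bp"].iloc[10]), int(sub["pos_bp"].iloc[14]))
        nil = simulate.simulate_nil(two_chrom_map, [seg_a, seg_b], rec, don)
        segs = bsa.detect_introgressions(nil, rec, don, two_chrom_map, min_run=3, max_gap_markers=1)
        assert len(segs) == 2

    def test_length_mismatch_errors(self, two_chrom_map, parents):
        rec, don = parents
        with pytest.raises(ValueError):
            bsa.detect_introgressions(rec[:-1], rec, don, two_chrom_map)


class TestFineMapInterval:
    def _population(self, genotype_rows, phenotypes):
        return simulate.Population(
            genotypes=np.array(genotype_rows, dtype=np.int8),
            phenotypes=np.array(phenotypes),
            provenance="imported",
        )

    def test_no_recombinants_returns_full_interval(self):
        mmap = manual_map([10, 20, 30, 40, 50])
        pop = self._population([[0, 0, 0, 0, 0]], ["mutant"])
        res = bsa.fine_map_interval(pop, mmap, ("chr1", 5_000_000, 55_000_000))
        assert (res.start_bp, res.end_bp) == (5_000_000, 55_000_000)

    def test_flanking_heterozygous_markers_bound_interval(self):
        # mutant het at markers 1 and 5, homozygous mutant at 2-4
        mmap = manual_map([10, 20, 30, 40, 50])
        pop = self._population([[1, 0, 0, 0, 1]], ["mutant"])
        res = bsa.fine_map_interval(pop, mmap, ("chr1", 5_000_000, 55_000_000))
        assert res.start_bp == 10_000_000 + 1
        assert res.end_bp == 50_000_000 - 1

    def test_heterozygous_wildtypes_exclude_nothing(self):
        mmap = manual_map([10, 20, 30, 40, 50])
        pop = self._population([[1, 0, 0, 0, 1], [0, 0, 1, 1, 1]], ["mutant", "wildtype"])
        res = bsa.fine_map_interval(pop, mmap, ("chr1", 5_000_000, 55_000_000))
        assert res.start_bp == 10_000_001 and res.end_bp == 49_999_999

    def test_wildtype_excludes_fully_homozygous_sub_interval(self):
        # mutant recombinants leave three disjoint feasible sub-intervals;
        # a wild-type line homozygous-mutant across the first two rules them out
        mmap = manual_map([10, 20, 30, 40, 50])
        pop = self._population(
            [[0, 1, 0, 0, 0], [0, 0, 0, 1, 0], [0, 0, 0, 0, 1]],
            ["mutant", "mutant", "wildtype"],
        )
        res = bsa.fine_map_interval(pop, mmap, ("chr1", 5_000_000, 55_000_000))
        assert res.start_bp == 40_000_001 and res.end_bp == 55_000_000

    def test_inconsistent_constraints_error(self):
        mmap = manual_map([10, 20, 30, 40, 50])
        pop = self._population([[0, 0, 1, 1, 1], [1, 1, 1, 0, 0]], ["mutant", "mutant"])
        with pytest.raises(ValueError, match="no consistent interval"):
            bsa.fine_map_interval(pop, mmap, ("chr1", 5_000_000, 55_000_000))

    def test_monotone_refinement(self):
        """Adding recombinant mutants never widens the interval."""
        mmap = simulate.build_marker_map(1, 30, 60_000_000, 1.0, seed=31)
        cross = CrossSpec(causal_loci=(CausalLocus("chr1", 30_000_000),), n_f2=313, seed=32)
        pop = simulate.simulate_f2(mmap, cross)
        interval = ("chr1", 1, 60_000_000)
        widths = []
        for n in (20, 80, 313):
            res = bsa.fine_map_interval(pop.subset(np.arange(n)), mmap, interval)
            widths.append(res.width_bp)
            assert res.start_bp <= 30_000_000 <= res.end_bp
        assert widths[0] >= widths[1] >= widths[2]
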