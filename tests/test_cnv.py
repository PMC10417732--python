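"""Copy-number core: bins, counting, GC normalization, CBS, states, clonality."""

import numpy as np
import pandas as pd
import pytest
from _oracles import (
    brute_force_clonality,
    brute_force_max_arc,
    interior_cuts,
    make_segset,
)

from crc_deconv import cnv


# ----------------------------------------------------------------------
# bins
# ----------------------------------------------------------------------

class TestMakeBins:
    def test_single_chromosome_equal_width(self):
        bins = cnv.make_bins({"chr1": 5_000_000}, 5000)
        assert len(bins) == 5000
        widths = bins["end"] - bins["start"]
        assert (widths == 1000).all()
        assert bins["end"].iloc[-1] == 5_000_000

    def test_allocation_proportional_to_length(self):
        bins = cnv.make_bins({"chrA": 3_000_000, "chrB": 1_000_000}, 1000)
        counts = bins["chrom"].value_counts()
        assert abs(counts["chrA"] - 750) <= 1
        assert abs(counts["chrB"] - 250) <= 1

    def test_bed_round_trip(self, tmp_path):
        bins = cnv.make_bins(cnv.default_genome(n_chrom=5), 500, seed=1)
        path = tmp_path / "bins.bed"
        cnv.write_bins_bed(bins, path)
        back = cnv.read_bins_bed(path)
        pd.testing.assert_frame_equal(bins, back, check_exact=False, rtol=1e-12)

    def test_gc_in_unit_interval(self):
        bins = cnv.make_bins(cnv.default_genome(), 5000, seed=0)
        assert bins["gc"].between(0, 1).all()

    def test_more_bins_than_bases_rejected(self):
        with pytest.raises(ValueError):
            cnv.make_bins({"chr1": 10}, 100)


class TestCountReads:
    def test_half_open_boundary(self):
        bins = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 100], "end": [100, 200], "gc": 0.4}
        )
        reads = pd.DataFrame({"chrom": ["c", "c", "c"], "pos": [99, 100, 199]})
        counts = cnv.count_reads(reads, bins)
        assert counts.tolist() == [1, 2]

    def test_empty_read_set(self):
        bins = cnv.make_bins({"c": 1000}, 10)
        assert cnv.count_reads(pd.DataFrame(columns=["chrom", "pos"]), bins).sum() == 0

    def test_uniform_reads_multinomial(self, rng):
        bins = cnv.make_bins({"c": 100_000}, 100)
        pos = rng.integers(0, 100_000, size=50_000)
        counts = cnv.count_reads(pd.DataFrame({"chrom": "c", "pos": pos}), bins)
        assert counts.sum() == 50_000
        expected = 500.0
        # each bin within 5 SD of the multinomial expectation
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))


# ----------------------------------------------------------------------
# GC normalization
# ----------------------------------------------------------------------

class TestGcNormalize:
    def test_constant_counts_give_unit_ratio(self):
        gc = np.linspace(0.35, 0.55, 500)
        ratios = cnv.gc_normalize(np.full(500, 80.0), gc)
        assert ratios == pytest.approx(np.ones(500), abs=1e-9)

    def test_injected_linear_bias_removed(self, rng):
        gc = rng.uniform(0.3, 0.6, 5000)
        lam = 100 * np.exp(2.0 * (gc - 0.45))
        counts = rng.poisson(lam)
        raw_corr = np.corrcoef(np.log(np.maximum(counts, 0.5)), gc)[0, 1]
        ratios = cnv.gc_normalize(counts, gc)
        corr = np.corrcoef(np.log(ratios), gc)[0, 1]
        assert abs(raw_corr) > 0.3
        assert abs(corr) < 0.05

    def test_median_is_exactly_one(self, rng):
        gc = rng.uniform(0.3, 0.6, 1001)
        counts = rng.poisson(60, size=1001)
        ratios = cnv.gc_normalize(counts, gc)
        assert abs(np.median(ratios) - 1.0) <= 1e-9

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            cnv.gc_normalize(np.zeros(500), np.linspace(0.3, 0.6, 500))

    def test_too_few_informative_bins_rejected(self):
        counts = np.zeros(500)
        counts[:50] = 10
        with pytest.raises(ValueError, match="100"):
            cnv.gc_normalize(counts, np.linspace(0.3, 0.6, 500))


# ----------------------------------------------------------------------
# CBS
# ----------------------------------------------------------------------

def one_chrom_bins(n):
    return pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 100, "end": (np.arange(n) + 1) * 100,
         "gc": 0.45}
    )


class TestSegmentCbs:
    def test_noiseless_step_single_breakpoint(self):
        ratios = np.concatenate([np.ones(100), np.full(100, 2.0)])
        segset = cnv.call_states(
            cnv.segment_cbs(ratios, one_chrom_bins(200), n_perm=200, seed=0)
        )
        seg = segset.segments
        assert len(seg) == 2
        assert seg["start_bin"].tolist() == [0, 100]
        assert segset.breakpoints() == [100]

    def test_constant_signal_single_segment(self):
        segset = cnv.segment_cbs(np.ones(150), one_chrom_bins(150), n_perm=200, seed=0)
        assert len(segset.segments) == 1

    def test_segments_partition_bin_axis(self, rng):
        ratios = np.exp(rng.normal(0, 0.1, 300))
        segset = cnv.segment_cbs(ratios, one_chrom_bins(300), n_perm=200, seed=1)
        seg = segset.segments.sort_values("start_bin")
        assert seg["start_bin"].iloc[0] == 0
        assert seg["end_bin"].iloc[-1] == 300
        assert (seg["end_bin"].to_numpy()[:-1] == seg["start_bin"].to_numpy()[1:]).all()

    def test_first_split_matches_brute_force_oracle(self, rng):
        """On <= 50-bin signals the chosen arc equals exhaustive search."""
        for trial in range(10):
            n = int(rng.integers(20, 51))
            cp = int(rng.integers(6, n - 6))
            x = rng.normal(0, 0.05, n)
            x[cp:] += rng.choice([-0.7, 0.7])
            stat_impl, arc_impl = cnv.max_arc_statistic(x)
            stat_oracle, arc_oracle = brute_force_max_arc(x)
            assert stat_impl == pytest.approx(stat_oracle, rel=1e-9)
            assert interior_cuts(arc_impl, n) == interior_cuts(arc_oracle, n)
            # the recovered boundary set includes the true change-point
            segset = cnv.segment_cbs(
                np.exp2(x), one_chrom_bins(n), n_perm=500, seed=trial
            )
            cuts = sorted(segset.segments["start_bin"])[1:]
            assert any(abs(c - cp) <= 1 for c in cuts)

    def test_calling_states_preserves_breakpoints(self, rng):
        ratios = np.concatenate([np.ones(80), np.full(60, 1.6), np.ones(80)])
        ratios *= np.exp(rng.normal(0, 0.05, 220))
        segset = cnv.segment_cbs(ratios, one_chrom_bins(220), n_perm=200, seed=2)
        called = cnv.call_states(segset)
        pd.testing.assert_frame_equal(
            segset.segments[["start_bin", "end_bin"]],
            called.segments[["start_bin", "end_bin"]],
        )

    def test_non_finite_ratios_rejected(self):
        with pytest.raises(cnv.SegmentationError):
            cnv.segment_cbs(np.array([1.0, np.nan, 1.0] * 10), one_chrom_bins(30))

    def test_low_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            cnv.segment_cbs(np.ones(20), one_chrom_bins(20), n_perm=50, seed=0)


class TestCallStates:
    @pytest.mark.parametrize(
        "mean_ratio,expected",
        [(1.3, "gain"), (1.0, "neutral"), (0.75, "neutral"), (1.25, "neutral"), (0.6, "loss")],
    )
    def test_threshold_semantics(self, mean_ratio, expected):
        seg = pd.DataFrame(
            [("chr1", 0, 10, mean_ratio, np.log2(mean_ratio), "")],
            columns=["chrom", "start_bin", "end_bin", "mean_ratio", "mean_log2", "state"],
        )
        called = cnv.call_states(cnv.SegmentSet("c", seg, 10))
        assert called.segments["state"].iloc[0] == expected


# ----------------------------------------------------------------------
# clonality
# ----------------------------------------------------------------------

class TestClonality:
    def test_two_cells_identical_breakpoints_form_group(self):
        cells = [
            make_segset("a", [0, 100, 250, 400], ["neutral", "gain", "neutral"], 400),
            make_segset("b", [0, 100, 250, 400], ["neutral", "gain", "neutral"], 400),
        ]
        res = cnv.detect_clonality(cells)
        assert res[0].clonal_group == res[1].clonal_group == "clone_1"
        assert all(r.rationale == "shared_breakpoints" for r in res)

    def test_all_neutral_cohort_no_groups(self):
        cells = [make_segset(c, [0, 400], ["neutral"], 400) for c in "abc"]
        res = cnv.detect_clonality(cells)
        assert all(not r.is_altered and r.clonal_group is None for r in res)

    def test_matches_brute_force_oracle(self, rng):
        """Random cohorts: grouping equals all-pairs matching + closure."""
        for trial in range(15):
            n_cells = int(rng.integers(4, 9))
            sets = []
            for i in range(n_cells):
                if rng.random() < 0.25:
                    sets.append(make_segset(f"c{i}", [0, 500], ["neutral"], 500))
                    continue
                n_bp = int(rng.integers(2, 5)) * 2
                bps = np.sort(rng.choice(np.arange(10, 490), n_bp, replace=False))
                while np.any(np.diff(bps) < 6):
                    bps = np.sort(rng.choice(np.arange(10, 490), n_bp, replace=False))
                bounds = [0, *bps.tolist(), 500]
                states = ["neutral" if k % 2 == 0 else "gain" for k in range(len(bounds) - 1)]
                sets.append(make_segset(f"c{i}", bounds, states, 500))
            res = cnv.detect_clonality(sets, breakpoint_tol_bins=2)
            impl_groups = {}
            for r in res:
                if r.clonal_group:
                    impl_groups.setdefault(r.clonal_group, []).append(r.cell_id)
            impl = sorted(sorted(v) for v in impl_groups.values())
            bp_sets = {s.cell_id: s.breakpoints() for s in sets}
            oracle = sorted(brute_force_clonality(bp_sets, tol=2))
            assert impl == oracle

    def test_order_invariance(self, rng):
        cells = [
            make_segset("a", [0, 100, 200, 500], ["neutral", "gain", "neutral"], 500),
            make_segset("b", [0, 101, 199, 500], ["neutral", "gain", "neutral"], 500),
            make_segset("c", [0, 300, 350, 500], ["neutral", "loss", "neutral"], 500),
        ]
        res_fwd = {r.cell_id: r.clonal_group for r in cnv.detect_clonality(cells)}
        res_rev = {r.cell_id: r.clonal_group for r in cnv.detect_clonality(cells[::-1])}
        assert res_fwd == res_rev
        assert res_fwd["a"] == res_fwd["b"] != None  # noqa: E711
        assert res_fwd["c"] is None

    def test_single_altered_cell_cancer_typical_rescue(self):
        bins = one_chrom_bins(500)
        lone = make_segset("x", [0, 100, 150, 500], ["neutral", "gain", "neutral"], 500)
        neutral = make_segset("y", [0, 500], ["neutral"], 500)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [16_000]})
        res = cnv.detect_clonality(
            [lone, neutral], cancer_typical_regions=regions, bins=bins
        )
        assert res[0].rationale == "cancer_typical_single"
        assert res[0].clonal_group == "single_x"
        # without the region list the lone cell stays ungrouped
        res2 = cnv.detect_clonality([lone, neutral])
        assert res2[0].clonal_group is None and res2[0].rationale == "none"

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            cnv.detect_clonality([], breakpoint_tol_bins=-1)
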