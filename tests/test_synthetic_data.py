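"""Synthetic-data generator: determinism, composition, counts, IMC, spike-ins."""

import numpy as np
import pandas as pd
import pytest

from crc_deconv import cnv
from crc_deconv import if_detection as ifd
from crc_deconv import synthetic_data as sd
from crc_deconv.config import PEMT_VIM_RANGE, ConfigError, SimulationConfig


class TestFrameGeneration:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=77, n_rare=20, n_wbc_per_frame=300)
        out = []
        for name in ("a.tsv", "b.tsv"):
            cells, _ = sd.generate_frame(cfg)
            sd.write_cell_table(cells, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_no_rare_cells(self):
        cfg = SimulationConfig(seed=1, n_rare=0, n_wbc_per_frame=400)
        cells, truth = sd.generate_frame(cfg)
        assert (truth == "WBC").all()
        assert len(ifd.detect_candidates(cells)) == 0

    def test_composition_apportionment_and_vim_range(self):
        cfg = SimulationConfig(
            seed=2,
            n_rare=100,
            n_wbc_per_frame=100,
            composition={"EPI.CTC": 0.6, "pEMT.CTC": 0.4},
        )
        cells, truth = sd.generate_frame(cfg)
        counts = truth.value_counts()
        assert counts["EPI.CTC"] == 60 and counts["pEMT.CTC"] == 40
        pemt_vim = cells.loc[cells["truth_label"] == "pEMT.CTC", "vim"]
        lo, hi = PEMT_VIM_RANGE
        assert ((pemt_vim >= lo) & (pemt_vim <= hi)).all()

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(composition={"EPI.CTC": 0.5, "CEC": 0.4})

    def test_child_streams_independent(self):
        """Requesting extra generators does not perturb existing streams."""
        cfg = SimulationConfig(seed=5, n_rare=5, n_wbc_per_frame=50)
        a, _ = sd.generate_frame(cfg)
        _ = sd.generate_spike_in(10, 1.0, cfg)
        b, _ = sd.generate_frame(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestGroundTruthProfiles:
    def test_clone_members_share_breakpoints(self, small_config, small_bins):
        truth = pd.Series(
            ["EPI.CTC", "pEMT.CTC", "CEC", "EPI.CTC"], index=list("abcd")
        )
        profiles = sd.profiles_for_labels(truth, small_bins, small_config)
        clonal = [p for p in profiles if p.clone_id == "clone_1"]
        assert len(clonal) == 3
        assert len({p.breakpoints for p in clonal}) == 1
        assert len(clonal[0].breakpoints) >= 2
        neutral = [p for p in profiles if p.clone_id == "neutral"]
        assert all(np.all(p.copy_numbers == 2) for p in neutral)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            sd.GroundTruthProfile("x", np.array([2, 2, 3, 3]), (1,), "c1")
        with pytest.raises(ValueError):
            sd.GroundTruthProfile("x", np.array([2, 3, 3, 2]), (1, 3), "neutral")


class TestReadCounts:
    def test_flat_profile_poisson_mean(self, small_bins):
        """No GC bias + flat genome: bin counts ~ Poisson(depth / n_bins)."""
        cfg = SimulationConfig(seed=3, gc_bias_strength=0.0, reads_per_cell=200_000, n_bins=800)
        # equal-width single chromosome so expected counts are exactly uniform
        bins = cnv.make_bins({"chr1": 800_000}, 800, seed=0)
        prof = sd.GroundTruthProfile("c0", np.full(800, 2), (), "neutral")
        counts = sd.simulate_read_counts([prof], bins, cfg).iloc[0].to_numpy()
        mean_expected = 200_000 / 800
        se = np.sqrt(mean_expected / 800)
        assert abs(counts.mean() - mean_expected) < 3 * se
        assert counts.min() >= 0 and np.issubdtype(counts.dtype, np.integer)

    def test_total_reads_near_configured_depth(self, small_config, small_bins):
        truth = pd.Series(["CEC"], index=["c0"])
        profiles = sd.profiles_for_labels(truth, small_bins, small_config)
        counts = sd.simulate_read_counts(profiles, small_bins, small_config)
        total = counts.to_numpy().sum()
        assert abs(total - small_config.reads_per_cell) < 5 * np.sqrt(
            small_config.reads_per_cell
        )

    def test_copy_number_doubles_expected_counts(self):
        cfg = SimulationConfig(seed=4, gc_bias_strength=0.0, reads_per_cell=300_000, n_bins=400)
        bins = cnv.make_bins({"chr1": 400_000}, 400, seed=0)
        cn = np.full(400, 2)
        cn[200:] = 4
        prof = sd.GroundTruthProfile("c0", cn, (200,), "c1")
        counts = sd.simulate_read_counts([prof], bins, cfg).iloc[0].to_numpy()
        ratio = counts[200:].mean() / counts[:200].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_zero_width_bins_rejected(self, small_config):
        bins = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [10], "gc": [0.4]})
        prof = sd.GroundTruthProfile("c0", np.array([2]), (), "neutral")
        with pytest.raises(ValueError, match="zero-width"):
            sd.simulate_read_counts([prof], bins, small_config)

    def test_same_seed_reproducible(self, small_config, small_bins):
        truth = pd.Series(["EPI.CTC", "CEC"], index=["a", "b"])
        profiles = sd.profiles_for_labels(truth, small_bins, small_config)
        c1 = sd.simulate_read_counts(profiles, small_bins, small_config)
        c2 = sd.simulate_read_counts(profiles, small_bins, small_config)
        pd.testing.assert_frame_equal(c1, c2)

    def test_negative_binomial_overdisperses(self, small_bins):
        base = dict(seed=8, gc_bias_strength=0.0, reads_per_cell=400_000, n_bins=800)
        bins = cnv.make_bins({"chr1": 800_000}, 800, seed=0)
        prof = sd.GroundTruthProfile("c0", np.full(800, 2), (), "neutral")
        var = {}
        for model in ("poisson", "negative_binomial"):
            cfg = SimulationConfig(noise_model=model, **base)
            counts = sd.simulate_read_counts([prof], bins, cfg).iloc[0].to_numpy()
            var[model] = counts.var() / counts.mean()
        assert var["negative_binomial"] > 2 * var["poisson"]


class TestImcSimulation:
    def test_cec_cd31_exceeds_wbc_by_construction(self):
        cfg = SimulationConfig(seed=6, imc_background_rate=0.0)
        labels = pd.Series(["CEC"] * 20, index=[f"c{i}" for i in range(20)])
        ions, background, refs = sd.simulate_imc(labels, sd.DEFAULT_PANEL, cfg)
        assert (background == 0).all()
        assert ions.loc[labels.index, "CD31"].min() > ions.loc[refs, "CD31"].max()

    def test_epcam_coexpression_subfraction_exact(self):
        cfg = SimulationConfig(seed=7, epcam_coexpression_fraction=0.5)
        labels = pd.Series(
            ["EPI.CTC"] * 120 + ["pEMT.CTC"] * 80, index=[f"c{i}" for i in range(200)]
        )
        ions, _, _ = sd.simulate_imc(labels, sd.DEFAULT_PANEL, cfg)
        high = (ions.loc[labels.index, "EpCAM"] > 1.0).sum()
        assert high == 100

    def test_empty_panel_rejected(self):
        cfg = SimulationConfig(seed=1)
        labels = pd.Series(["CEC"], index=["c0"])
        with pytest.raises(ValueError, match="panel"):
            sd.simulate_imc(labels, sd.DEFAULT_PANEL.iloc[0:0], cfg)


class TestSpikeIn:
    @pytest.mark.parametrize("conc,expected", [(430, 430), (100, 100), (0, 0)])
    def test_spiked_cell_counts(self, conc, expected):
        cfg = SimulationConfig(seed=9, n_wbc_per_frame=200)
        frame = sd.generate_spike_in(conc, 1.0, cfg)
        assert (frame["truth_label"] == "SPIKE").sum() == expected
        assert (frame["truth_label"] == "WBC").sum() == 200

    def test_spiked_cells_have_endothelial_profile(self):
        cfg = SimulationConfig(seed=10, n_wbc_per_frame=300)
        frame = sd.generate_spike_in(50, 1.0, cfg)
        spiked = frame[frame["truth_label"] == "SPIKE"]
        wbc = frame[frame["truth_label"] == "WBC"]
        assert spiked["vim"].median() > 5 * wbc["vim"].median()
        assert spiked["cd45"].max() < wbc["cd45"].quantile(0.01)
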