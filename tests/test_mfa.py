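import numpy as np
import pytest

from replimode import simdata
from replimode.genomeio import circular_distance
from replimode.mfa import (
    CoverageProfile,
    OutlierParams,
    bin_coverage,
    correct_coverage,
    infer_replication_direction,
    remove_outliers,
    synchrony_ratios,
)
from tests.conftest import corrected_profile


class TestBinCoverage:
    def test_constant_depth(self):
        prof = bin_coverage(np.full(2500, 10), 1000)
        assert prof.bin_values.tolist() == [10, 10, 10]

    def test_partial_final_bin_uses_actual_width(self):
        prof = bin_coverage(np.array([1, 2, 3, 4]), 2)
        assert prof.bin_values.tolist() == [1.5, 3.5]

    def test_zero_bin_size_errors(self):
        with pytest.raises(ValueError):
            bin_coverage(np.ones(10), 0)


class TestCorrectCoverage:
    def test_flat_stationary_is_identity(self):
        exp = bin_coverage(np.arange(5000) % 7 + 10.0, 1000, "a")
        stat = bin_coverage(np.full(5000, 20.0), 1000, "a", phase="stationary")
        corrected = correct_coverage(exp, stat)
        assert np.allclose(corrected.bin_values, exp.bin_values)
        assert corrected.corrected

    def test_high_stationary_bin_halves_exponential(self):
        exp = CoverageProfile("a", 4000, 1000, np.array([30.0, 30, 30, 30]))
        stat = CoverageProfile(
            "a", 4000, 1000, np.array([40.0, 60, 20, 40]), phase="stationary"
        )
        # wait: replicon mean is 40; bin 1 factor = 60/40 = 1.5
        corrected = correct_coverage(exp, stat)
        assert np.allclose(corrected.bin_values, [30.0, 20.0, 60.0, 30.0])

    def test_exp_equals_stat_gives_constant(self):
        rng = np.random.default_rng(0)
        depth = rng.poisson(50, size=20_000).astype(float)
        exp = bin_coverage(depth, 1000, "a")
        stat = bin_coverage(depth, 1000, "a", phase="stationary")
        corrected = correct_coverage(exp, stat)
        assert np.allclose(corrected.bin_values, stat.bin_values.mean())

    def test_zero_stationary_bin_masked_not_divided(self):
        exp = CoverageProfile("a", 3000, 1000, np.array([10.0, 10, 10]))
        stat = CoverageProfile(
            "a", 3000, 1000, np.array([20.0, 0, 40]), phase="stationary"
        )
        corrected = correct_coverage(exp, stat)
        assert corrected.mask.tolist() == [False, True, False]
        assert np.isfinite(corrected.bin_values).all()

    def test_binning_mismatch_errors(self):
        a = CoverageProfile("a", 3000, 1000, np.zeros(3))
        b = CoverageProfile("a", 4000, 1000, np.zeros(4), phase="stationary")
        with pytest.raises(ValueError):
            correct_coverage(a, b)

    def test_removes_planted_shared_bias_field(self):
        """Correction recovers the bias-free expectation to < 3% RMS."""
        cfg = simdata.SimReplicon(
            id="r", length=1_000_000, mode="bidirectional", ori=0, C=1.0,
            bias_sigma=0.15, seed=5,
        )
        cov = simdata.simulate_coverage(
            [cfg], simdata.GrowthModel(tau=1.0), mean_depth=200, seed=5
        )
        exp = bin_coverage(cov.exponential["r"], 1000, "r")
        stat = bin_coverage(cov.stationary["r"], 1000, "r", phase="stationary")
        corrected = correct_coverage(exp, stat)
        bias_free = bin_coverage(
            cov.expected_exponential["r"]
            / np.repeat(cov.bias_fields["r"], 1000)[:1_000_000],
            1000, "r",
        )
        rel = (corrected.bin_values - bias_free.bin_values) / bias_free.bin_values
        assert np.sqrt((rel**2).mean()) < 0.03


class TestRemoveOutliers:
    def test_single_spike_on_flat_profile_masked_exactly(self):
        values = np.full(3000, 50.0)
        values[1234] = 500.0
        prof = CoverageProfile("f", 3_000_000, 1000, values)
        masked = remove_outliers(prof)
        assert masked.mask.sum() == 1
        assert masked.mask[1234]

    def test_flat_profile_masks_nothing(self):
        prof = CoverageProfile("f", 200_000, 1000, np.full(200, 50.0))
        assert remove_outliers(prof).mask.sum() == 0

    def test_too_few_bins_errors(self):
        prof = CoverageProfile("f", 30_000, 1000, np.full(30, 50.0))
        with pytest.raises(ValueError):
            remove_outliers(prof)

    def test_neighbors_must_be_even(self):
        with pytest.raises(ValueError):
            OutlierParams(neighbors=51)

    def test_planted_spikes_masked_clean_bins_kept(self):
        cfg = simdata.SimReplicon(
            id="r", length=1_000_000, mode="bidirectional", ori=0, C=1.0, seed=5
        )
        cov = simdata.simulate_coverage(
            [cfg], simdata.GrowthModel(tau=1.0), mean_depth=200, seed=5
        )
        spiked, starts = simdata.plant_spikes(
            cov.exponential["r"], 20, 5.0, seed=9
        )
        exp = bin_coverage(spiked, 1000, "r")
        stat = bin_coverage(cov.stationary["r"], 1000, "r", phase="stationary")
        masked = remove_outliers(correct_coverage(exp, stat))
        spike_bins = set(starts // 1000)
        hit = set(np.flatnonzero(masked.mask))
        assert len(spike_bins & hit) >= 18
        assert len(hit - spike_bins) <= 0.01 * (1000 - 20)

    def test_idempotent_on_own_output(self):
        cfg = simdata.SimReplicon(
            id="r", length=500_000, mode="bidirectional", ori=0, C=1.0, seed=6
        )
        cov = simdata.simulate_coverage(
            [cfg], simdata.GrowthModel(tau=1.0), mean_depth=100, seed=6
        )
        spiked, _ = simdata.plant_spikes(cov.exponential["r"], 10, 5.0, seed=3)
        once = remove_outliers(bin_coverage(spiked, 1000, "r"))
        twice = remove_outliers(once)
        assert (once.mask == twice.mask).all()


class TestInferReplicationDirection:
    def test_bidirectional_chromosome(self, termination_sim, termination_profiles):
        main, _, _, _ = termination_sim
        fit = infer_replication_direction(termination_profiles["chr1"])
        assert fit.model == "bidirectional"
        assert circular_distance(fit.ter_est, main.ter, main.length) <= 10_000
        assert circular_distance(fit.ori_est, main.ori, main.length) <= 10_000

    def test_unidirectional_chromid_single_negative_slope(
        self, termination_sim, termination_profiles
    ):
        _, chromid, _, _ = termination_sim
        fit = infer_replication_direction(termination_profiles["chr2"])
        assert fit.model == "unidirectional"
        assert len(fit.slopes) == 1 and fit.slopes[0] < 0
        assert circular_distance(fit.ori_est, chromid.ori, chromid.length) <= 10_000

    def test_stationary_profile_returns_flat_with_warning(self, caplog):
        prof = CoverageProfile(
            "s", 200_000, 1000, np.full(200, 50.0), phase="stationary"
        )
        with caplog.at_level("WARNING"):
            fit = infer_replication_direction(prof)
        assert fit.model == "flat"
        assert any("stationary" in r.message for r in caplog.records)

    def test_flat_noise_profile_selects_flat(self):
        rng = np.random.default_rng(4)
        depth = rng.poisson(100 * 1000, size=300) / 1000.0
        prof = CoverageProfile("f", 300_000, 1000, depth)
        assert infer_replication_direction(prof).model == "flat"

    def test_mostly_masked_errors(self):
        prof = CoverageProfile(
            "m", 200_000, 1000, np.full(200, 50.0),
            mask=np.arange(200) < 120,
        )
        with pytest.raises(ValueError):
            infer_replication_direction(prof)

    def test_depth_scale_invariance(self, termination_sim):
        _, _, _, cov = termination_sim
        p1 = remove_outliers(bin_coverage(cov.exponential["chr1"], 1000, "chr1"))
        p4 = remove_outliers(
            bin_coverage(cov.exponential["chr1"] * 4, 1000, "chr1")
        )
        f1 = infer_replication_direction(p1)
        f4 = infer_replication_direction(p4)
        assert f1.model == f4.model
        assert f1.ori_est == f4.ori_est and f1.ter_est == f4.ter_est

    def test_log2_drop_matches_replication_budget(
        self, termination_sim, termination_profiles
    ):
        """Fitted ori-to-ter log2 drop equals C/tau within 5%."""
        main, chromid, growth, _ = termination_sim
        fit1 = infer_replication_direction(termination_profiles["chr1"])
        assert abs(fit1.log2_drop - main.C / growth.tau) / (main.C / growth.tau) < 0.05
        fit2 = infer_replication_direction(termination_profiles["chr2"])
        # single-fork drop extrapolates over the short terminal gap:
        # expected full-circle drop is (C/tau) * L/(L - gap)
        expected = (chromid.C / growth.tau) * chromid.length / (
            chromid.length - chromid.ter_offset
        )
        assert abs(fit2.log2_drop - expected) / expected < 0.05


class TestSynchrony:
    def test_termination_synchrony_recovered(
        self, termination_sim, termination_profiles
    ):
        main, chromid, _, _ = termination_sim
        res = synchrony_ratios(
            termination_profiles["chr1"], termination_profiles["chr2"],
            {"ori": main.ori, "dif": main.ter},
            {"ori": chromid.ori, "dif": chromid.ter},
        )
        assert res.mode == "termination_synchrony"
        assert abs(res.R_dif - 1.0) <= 0.1
        assert res.R_ori > 1.15

    def test_stationary_pair_indeterminate(self, termination_sim):
        main, chromid, _, cov = termination_sim
        profs = {}
        for r in (main, chromid):
            profs[r.id] = bin_coverage(
                cov.stationary[r.id], 1000, r.id, phase="stationary"
            )
        res = synchrony_ratios(
            profs["chr1"], profs["chr2"],
            {"ori": main.ori, "dif": main.ter},
            {"ori": chromid.ori, "dif": chromid.ter},
        )
        assert res.mode == "indeterminate"
        assert abs(res.R_ori - 1.0) < 0.1 and abs(res.R_dif - 1.0) < 0.1

    def test_initiation_synchrony_recovered(self):
        main = simdata.SimReplicon(
            id="chr1", length=2_000_000, mode="bidirectional", ori=0, C=1.0, seed=21
        )
        # bidirectional chromid: its ori region is smooth, so R_ori sits at
        # 1 under shared initiation (a unidirectional chromid's ori abuts
        # its ter, which biases any symmetric ori window upward)
        chromid = simdata.SimReplicon(
            id="chr2", length=600_000, mode="bidirectional", ori=50_000,
            C=0.5, seed=22,
        )
        growth = simdata.GrowthModel(tau=1.0, synchrony="initiation")
        cov = simdata.simulate_coverage([main, chromid], growth, 200, seed=23)
        p1 = corrected_profile(cov, "chr1", main.length)
        p2 = corrected_profile(cov, "chr2", chromid.length)
        res = synchrony_ratios(
            p1, p2,
            {"ori": main.ori, "dif": main.ter},
            {"ori": chromid.ori, "dif": chromid.ter},
        )
        assert res.mode == "initiation_synchrony"
        assert res.R_dif < 0.85

    def test_all_masked_region_errors(self):
        prof = CoverageProfile(
            "a", 100_000, 1000, np.full(100, 50.0),
            mask=np.ones(100, dtype=bool),
        )
        with pytest.raises(ValueError):
            synchrony_ratios(
                prof, prof, {"ori": 0, "dif": 50_000}, {"ori": 0, "dif": 50_000}
            )

    def test_missing_site_errors(self, termination_profiles):
        with pytest.raises(ValueError, match="dif"):
            synchrony_ratios(
                termination_profiles["chr1"], termination_profiles["chr2"],
                {"ori": 0}, {"ori": 0, "dif": 1},
            )
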