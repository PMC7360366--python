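"""Response index, significance classes, sparseness, bootstrap test,
latency/peak, tuning correlation, spike phase, PPC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import odorstate as od
from odorstate.responsivity import ppc_pair_sum, rank_sum_p


def roc_auc_threshold_sweep(pos, neg):
    """Brute-force ROC: sweep every threshold, trapezoidal area."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    thresholds = np.concatenate([[-np.inf],
                                 np.unique(np.concatenate([pos, neg])),
                                 [np.inf]])
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    return -np.trapezoid(tpr, fpr)


class TestAuroc:
    def test_perfect_separation(self):
        _, idx = od.auroc_response_index([4, 5, 6], [1, 2, 3])
        assert idx == 1.0
        _, idx = od.auroc_response_index([1, 2, 3], [4, 5, 6])
        assert idx == -1.0

    def test_identical_samples_give_zero(self):
        _, idx = od.auroc_response_index([2, 3, 4], [2, 3, 4])
        assert idx == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_example(self):
        auroc, idx = od.auroc_response_index([2, 4], [1, 3])
        assert auroc == pytest.approx(0.75)
        assert idx == pytest.approx(0.5)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 20, 2)
            pos = rng.poisson(rng.uniform(0.5, 8), n1)
            neg = rng.poisson(rng.uniform(0.5, 8), n2)
            auroc, _ = od.auroc_response_index(pos, neg)
            assert abs(auroc - roc_auc_threshold_sweep(pos, neg)) < 1e-12

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            od.auroc_response_index([1], [2, 3])


class TestClassifyResponse:
    def test_identical_is_ns(self):
        assert od.classify_response([3, 3, 3, 3], [3, 3, 3, 3]) == "ns"

    def test_strong_activation_matches_enumeration(self):
        evoked = [20, 22, 19, 21, 20, 23, 21]
        baseline = [2, 1, 3, 2, 2, 1, 2]
        assert od.classify_response(evoked, baseline) == "activated"
        # exact enumeration oracle: all evoked > all baseline, two-sided
        # p = 2 / C(14, 7)
        from math import comb
        assert rank_sum_p(evoked, baseline) == pytest.approx(
            2 / comb(14, 7), rel=1e-6)

    def test_suppression_detected(self):
        assert od.classify_response([0, 1, 0, 0, 1, 0, 0],
                                    [5, 6, 4, 5, 7, 5, 6]) == "suppressed"

    def test_alpha_one_classifies_everything_nontied(self):
        assert od.classify_response([3, 4, 5], [1, 2, 3], alpha=1.0) \
            == "activated"

    def test_all_zero_warns_ns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert od.classify_response([0, 0, 0], [0, 0, 0]) == "ns"


class TestCrossStateClass:
    @pytest.mark.parametrize("aw,kx,label", [
        ("activated", "activated", "robust"),
        ("activated", "ns", "awake_only"),
        ("ns", "activated", "kx_only"),
        ("suppressed", "activated", "kx_only"),
        ("activated", "suppressed", "awake_only"),
        ("suppressed", "suppressed", "none"),
        ("ns", "ns", "none"),
    ])
    def test_rule(self, aw, kx, label):
        assert od.classify_cross_state(aw, kx) == label

    def test_recovers_ground_truth_at_high_snr(self):
        # large, fast, reliable responses -> activated labels recovered
        cfg = od.SimConfig(n_cells_per_region=20, n_trials_awake=7,
                           n_trials_kx=7, pre_s=2.5, post_s=2.0,
                           amp_params={"mean_hz": 60.0, "sigma_log": 0.2},
                           latency_params={"robust": (0.03, 0.005),
                                           "state_specific": (0.05, 0.01)},
                           gain_sd=0.0)
        b, gt = od.generate_session(cfg, "pcx", seed=3)
        feats = od.extract_features(b)
        from odorstate.pipeline import stage_responsivity
        res = stage_responsivity(feats)
        merged = res["cross_state"].merge(
            gt.cell_odor[["unit_id", "odor_id", "class"]],
            on=["unit_id", "odor_id"])
        robust_true = merged["class"] == "robust"
        assert robust_true.sum() >= 5
        sens = (merged.loc[robust_true, "label"] == "robust").mean()
        assert sens >= 0.9


class TestSparseness:
    def test_one_hot_is_maximal(self):
        assert od.lifetime_sparseness([0, 0, 5, 0]) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert od.lifetime_sparseness([3, 3, 3, 3]) == pytest.approx(0.0)

    def test_hand_value(self):
        # r = (1,1,2): S = (1 - (4/3)^2 / 2) / (2/3) = 1/6
        assert od.lifetime_sparseness([1, 1, 2]) == pytest.approx(1 / 6)

    def test_all_zero_flagged(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert np.isnan(od.lifetime_sparseness([0, 0, 0]))

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_bounded_unit_interval(self, rates):
        s = od.lifetime_sparseness(rates)
        assert -1e-9 <= s <= 1 + 1e-9


class TestBootstrapDifference:
    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        b = rng.normal(10, 1, 50)
        res = od.bootstrap_difference_test(a, b, n_boot=1000, seed=1)
        assert res["p"] <= 2 / 1000

    def test_determinism(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        r1 = od.bootstrap_difference_test(a, b, seed=42)
        r2 = od.bootstrap_difference_test(a, b, seed=42)
        assert r1["p"] == r2["p"] and r1["ci_a"] == r2["ci_a"]

    def test_null_calibration(self):
        # same-distribution groups: p approximately uniform on (0, 1]
        rng = np.random.default_rng(2)
        ps = []
        for i in range(200):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 1, 25)
            ps.append(od.bootstrap_difference_test(a, b, n_boot=200,
                                                   seed=i)["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_ci_covers_estimate(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(2, 1, 40), rng.normal(0, 1, 40)
        res = od.bootstrap_difference_test(a, b, seed=0)
        assert res["ci_a"][0] <= res["estimate_a"] <= res["ci_a"][1]

    def test_small_n_boot_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            od.bootstrap_difference_test([1, 2, 3], [4, 5, 6], n_boot=50,
                                         seed=0)


class TestLatencyPeak:
    def test_step_onset_recovered(self):
        bin_s = 0.01
        rng = np.random.default_rng(0)
        psth = 5.0 + rng.normal(0, 0.5, 200)
        psth[100 + 6:] += 50.0  # step at 60 ms after alignment (bin 100)
        lat, peak = od.response_latency_peak(psth, bin_s, 100, smooth_sd_s=0)
        assert abs(lat - 0.06) <= bin_s
        assert peak == pytest.approx(55.0, rel=0.05)

    def test_flat_psth_undefined(self):
        rng = np.random.default_rng(0)
        psth = 5 + rng.normal(0, 0.2, 200)
        lat, _ = od.response_latency_peak(psth, 0.01, 100)
        assert np.isnan(lat)

    def test_zero_variance_baseline_warns(self):
        psth = np.zeros(200)
        psth[120:] = 10.0
        with pytest.warns(UserWarning, match="zero baseline"):
            lat, _ = od.response_latency_peak(psth, 0.01, 100)
        assert np.isfinite(lat)

    def test_generator_latency_recovered(self):
        # high-SNR simulated transient: recover the planted onset latency
        cfg = od.SimConfig(n_cells_per_region=1, n_trials_awake=30,
                           n_trials_kx=7, n_odors=1, pre_s=2.0, post_s=2.0,
                           amp_params={"mean_hz": 80.0, "sigma_log": 0.01},
                           latency_params={"robust": (0.08, 1e-6),
                                           "state_specific": (0.08, 1e-6)},
                           gain_sd=0.0, drift_amp=0.0, sniff_amp_exponent=0.0,
                           class_probs={"robust": 1.0, "awake_only": 0,
                                        "kx_only": 0, "suppressed": 0})
        errors = []
        for seed in range(8):
            b, gt = od.generate_session(cfg, "pcx", seed=seed)
            feats = od.extract_features(b, qc=False)
            aw = feats.trial_labels.state == "awake"
            t0 = feats.alignment.loc[aw.to_numpy(), "response_inh_s"].to_numpy()
            w = od.WindowSpec(-1.0, 0.01, 200)
            tensor = od.count_spikes(b.spikes, t0, w)
            psth = tensor.counts[0].mean(axis=0) / w.bin_s
            lat, _ = od.response_latency_peak(psth, w.bin_s, 100)
            errors.append(lat - gt.cell_odor.latency_s.iloc[0])
        assert abs(np.mean(errors)) < 0.03

    def test_invalid_baseline_epoch(self):
        with pytest.raises(ValueError):
            od.response_latency_peak(np.zeros(10), 0.01, 0)


class TestTuningCorrelation:
    def test_identity_and_reversal(self):
        assert od.tuning_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == \
            pytest.approx(1.0)
        assert od.tuning_correlation(np.arange(1, 7),
                                     np.arange(6, 0, -1)) == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(od.tuning_correlation([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            od.tuning_correlation([1, 2, 3], [1, 2])

    def test_noise_attenuation(self):
        # r between t and t + noise approaches 1/sqrt(1 + s^2/var) on
        # average; with noise on both vectors the product of attenuations
        rng = np.random.default_rng(4)
        var_t, s2 = 4.0, 1.0
        expected = 1.0 / (1.0 + s2 / var_t)
        rs = []
        for _ in range(400):
            t = rng.normal(0, np.sqrt(var_t), 6)
            a = t + rng.normal(0, np.sqrt(s2), 6)
            b = t + rng.normal(0, np.sqrt(s2), 6)
            rs.append(od.tuning_correlation(a, b))
        assert abs(np.mean(rs) - expected) < 0.05


class TestSpikePhase:
    def test_anchor_conventions(self):
        inh = np.array([0.0, 1.0, 2.0])
        exh = np.array([0.4, 1.4])
        ph = od.spike_phase([0.0, 0.2, 0.4, 0.7, 1.0], inh, exh)
        np.testing.assert_allclose(ph, [0, 90, 180, 270, 0], atol=1e-9)

    def test_outside_cycle_is_nan(self):
        ph = od.spike_phase([5.0], np.array([0.0, 1.0]), np.array([0.4]))
        assert np.isnan(ph[0])


class TestPPC:
    def test_closed_forms(self):
        assert od.ppc([10, 10, 10, 10]) == pytest.approx(1.0)
        assert od.ppc([0, 180]) == pytest.approx(-1.0)
        assert od.ppc([0, 90, 180, 270]) == pytest.approx(-1 / 3)

    def test_matches_pair_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ph = rng.uniform(0, 360, rng.integers(2, 40))
            assert od.ppc(ph) == pytest.approx(ppc_pair_sum(ph), abs=1e-10)

    def test_uniform_phases_expect_zero(self):
        rng = np.random.default_rng(6)
        vals = [od.ppc(rng.uniform(0, 360, 50)) for _ in range(1000)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-4

    def test_too_few_spikes(self):
        with pytest.warns(UserWarning):
            assert np.isnan(od.ppc([90.0]))
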