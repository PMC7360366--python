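"""Sniff detection, alignment, counting, QC, and trial selection."""

import numpy as np
import pandas as pd
import pytest

import odorstate as od
from odorstate.preprocess import (SniffDetectionError, WindowSpec,
                                  apply_stability_criteria, session_unit_rates)
from odorstate.session import AWAKE, KX


class TestDetectInhalations:
    def test_sinusoid_crossings(self):
        # 2 Hz sinusoid, 10 s: inhalation = negative-going zero crossing
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        airflow = np.sin(2 * np.pi * 2 * t)  # negative-going at 0.5, 1.0, ...
        ev = od.detect_inhalations(airflow, fs)
        assert ev.inhalation_onsets.size == 20
        spacing = np.diff(ev.inhalation_onsets)
        np.testing.assert_allclose(spacing, 0.5, atol=2 / fs)

    def test_noise_robustness(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        clean = np.sin(2 * np.pi * 2 * t)
        rng = np.random.default_rng(0)
        noisy = clean + 0.10 * rng.standard_normal(t.size)
        ref = od.detect_inhalations(clean, fs).inhalation_onsets
        got = od.detect_inhalations(noisy, fs).inhalation_onsets
        assert got.size == ref.size
        np.testing.assert_allclose(got, ref, atol=25 / fs)

    def test_all_positive_trace_warns(self):
        with pytest.warns(UserWarning, match="no inhalations"):
            ev = od.detect_inhalations(np.abs(np.sin(np.linspace(0, 20, 2000)))
                                       + 0.1, 200.0)
        assert ev.inhalation_onsets.size == 0

    def test_invalid_traces_rejected(self):
        with pytest.raises(SniffDetectionError):
            od.detect_inhalations(np.full(1000, np.nan), 200.0)
        with pytest.raises(SniffDetectionError):
            od.detect_inhalations(np.zeros(1000), 200.0)
        with pytest.raises(ValueError, match="sample rate"):
            od.detect_inhalations(np.sin(np.arange(100.0)), 50.0)


class TestAlignTrials:
    def test_inclusive_tie_at_odor_onset(self):
        b = od.make_fixture("tiny-2odor")
        resp = b.respiration
        ev = od.SniffEvents(resp.inhalation_onsets, resp.exhalation_onsets)
        aligned = od.align_trials(ev, b.trials).trial_alignment
        # odor_on falls exactly on an inhalation onset -> that inhalation
        np.testing.assert_allclose(aligned["response_inh_s"],
                                   b.trials["odor_on_s"], atol=1e-9)
        # baseline = previous breath, 0.5 s earlier; offset at odor_off
        np.testing.assert_allclose(aligned["baseline_inh_s"],
                                   b.trials["odor_on_s"] - 0.5, atol=1e-9)
        np.testing.assert_allclose(aligned["offset_inh_s"],
                                   b.trials["odor_off_s"], atol=1e-9)
        np.testing.assert_allclose(aligned["first_breath_s"], 0.5, atol=1e-9)

    def test_trial_without_inhalation_flagged(self):
        ev = od.SniffEvents(np.array([1.0, 2.0]), np.array([1.2, 2.2]))
        trials = pd.DataFrame({"trial_index": [0, 1],
                               "odor_id": [0, 0],
                               "odor_on_s": [1.5, 5.0],
                               "odor_off_s": [1.6, 5.1],
                               "state": [AWAKE, AWAKE]})
        table = od.align_trials(ev, trials).trial_alignment
        assert table.loc[0, "valid"]
        assert not table.loc[1, "valid"]

    def test_simulated_first_breath_matches_generator(self, pcx_session):
        bundle, gt = pcx_session
        feats = od.extract_features(bundle, qc=False)
        merged = feats.alignment.merge(gt.trial_factors, on="trial_index")
        err = np.abs(merged["first_breath_s_x"] - merged["first_breath_s_y"])
        # an inhalation within a sample of odor onset can shift which
        # breath counts as first; allow rare boundary off-by-one breaths
        assert (err < 0.02).mean() >= 0.95


class TestCountSpikes:
    def test_basic_and_half_open_convention(self):
        spikes = {0: np.array([0.1, 0.2, 0.48])}
        w = WindowSpec(0.0, 0.48, 1)
        tensor = od.count_spikes(spikes, np.array([0.0]), w)
        assert tensor.counts[0, 0, 0] == 2  # spike at 0.48 excluded
        # spike exactly at window start is counted
        tensor = od.count_spikes({0: np.array([0.0])}, np.array([0.0]), w)
        assert tensor.counts[0, 0, 0] == 1

    def test_bins_tile_window_and_sum_matches_interval(self):
        rng = np.random.default_rng(1)
        spikes = {0: np.sort(rng.uniform(0, 10, 300))}
        w = WindowSpec(-0.5, 0.03, 40)  # sliding-style multi-bin window
        aligns = np.array([2.0, 5.0, 7.5])
        tensor = od.count_spikes(spikes, aligns, w)
        direct = od.count_in_intervals(spikes, aligns + w.start_s,
                                       aligns + w.start_s + w.duration_s)
        np.testing.assert_array_equal(tensor.counts.sum(axis=2), direct)

    def test_poisson_mean_matches_rate(self):
        rng = np.random.default_rng(2)
        rate, dur = 20.0, 2000.0
        spikes = {0: np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))}
        aligns = np.arange(0.0, dur - 1, 1.0)
        w = WindowSpec(0.0, 0.48, 1)
        tensor = od.count_spikes(spikes, aligns, w)
        mean = tensor.counts.mean()
        se = np.sqrt(rate * 0.48 / aligns.size)
        assert abs(mean - rate * 0.48) < 4 * se

    def test_duplicate_trial_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            od.count_spikes({0: np.array([0.1])}, np.array([0.0, 1.0]),
                            WindowSpec(0, 0.5, 1), trial_ids=np.array([3, 3]))


class TestStabilityCriteria:
    def test_qc_edge_fixture(self):
        b = od.make_fixture("qc-edge-cases")
        qc = apply_stability_criteria(b.units).set_index("unit_id")
        assert qc.loc[0, "keep"]        # exactly 0.01 Hz kept
        assert qc.loc[1, "keep"]        # exactly 100-fold kept
        assert not qc.loc[2, "keep"]    # 51 uV amplitude change discarded
        assert qc.loc[2, "reasons"] == "amplitude delta"
        assert qc.loc[3, "keep"]

    def test_ratio_above_threshold_discarded(self):
        units = pd.DataFrame([(0, "ob", 150.0, 150.0, 2.0, 0.015, 0.6)],
                             columns=od.make_fixture("qc-edge-cases").units.columns)
        qc = apply_stability_criteria(units)
        assert not qc.loc[0, "keep"]
        assert np.isclose(qc.loc[0, "rate_ratio"], 2.0 / 0.015)

    def test_missing_state_unevaluable(self):
        units = pd.DataFrame([(0, "ob", 150.0, np.nan, 2.0, 1.0, 0.6)],
                             columns=od.make_fixture("qc-edge-cases").units.columns)
        qc = apply_stability_criteria(units)
        assert not qc.loc[0, "keep"]
        assert "missing state" in qc.loc[0, "reasons"]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = 200
        units = pd.DataFrame({
            "unit_id": np.arange(n),
            "region": "ob",
            "amp_awake_uv": rng.uniform(50, 300, n),
            "amp_kx_uv": rng.uniform(50, 300, n),
            "rate_awake_hz": 10 ** rng.uniform(-3, 1.5, n),
            "rate_kx_hz": 10 ** rng.uniform(-3, 1.5, n),
            "peak_trough_ms": 0.6,
        })
        qc = apply_stability_criteria(units)
        for _, u in units.iterrows():
            keep = True
            if (u.rate_awake_hz + u.rate_kx_hz) / 2 < 0.01:
                keep = False
            if max(u.rate_awake_hz, u.rate_kx_hz) / \
                    min(u.rate_awake_hz, u.rate_kx_hz) > 100:
                keep = False
            if abs(u.amp_awake_uv - u.amp_kx_uv) > 50:
                keep = False
            assert qc.loc[qc.unit_id == u.unit_id, "keep"].item() == keep

    def test_qc_idempotent_and_order_independent(self):
        b = od.make_fixture("qc-edge-cases")
        qc1 = apply_stability_criteria(b.units)
        shuffled = b.units.sample(frac=1.0, random_state=0)
        qc2 = apply_stability_criteria(shuffled).sort_values("unit_id")
        np.testing.assert_array_equal(qc1["keep"].to_numpy(),
                                      qc2["keep"].to_numpy())

    def test_session_unit_rates_denominator(self):
        b = od.make_fixture("qc-edge-cases")
        rates = session_unit_rates(b)
        # 5 spikes spread over 100 s, onset at 50 s
        st = b.spikes[0]
        n_aw = (st < 50.0).sum()
        assert np.isclose(rates.loc[0, "rate_awake_hz"], n_aw / 50.0)


class TestSelectStateTrials:
    def _trials(self, n_awake=15, n_kx=7):
        rows = []
        idx = 0
        t = 0.0
        for state, n in ((AWAKE, n_awake), (KX, n_kx)):
            for _ in range(n):
                for odor in (0, 1):
                    rows.append((idx, odor, t + 2, t + 3, state))
                    t += 10.0
                    idx += 1
        return pd.DataFrame(rows, columns=["trial_index", "odor_id",
                                           "odor_on_s", "odor_off_s", "state"]), t

    def test_last_seven_awake_selected(self):
        trials, _ = self._trials()
        onset = trials[trials.state == AWAKE]["odor_off_s"].max() + 1
        sel = od.select_state_trials(trials, onset)
        for odor in (0, 1):
            awake = trials[(trials.state == AWAKE) & (trials.odor_id == odor)]
            assert list(sel[odor][AWAKE]) == list(awake.trial_index)[-7:]
            kx = trials[(trials.state == KX) & (trials.odor_id == odor)]
            assert list(sel[odor][KX]) == list(kx.trial_index)[:7]

    def test_exactly_seven_all_selected(self):
        trials, _ = self._trials(n_awake=7)
        onset = trials[trials.state == AWAKE]["odor_off_s"].max() + 1
        sel = od.select_state_trials(trials, onset)
        assert len(sel[0][AWAKE]) == 7

    def test_insufficient_trials_names_odor(self):
        trials, _ = self._trials(n_awake=5)
        onset = trials[trials.state == AWAKE]["odor_off_s"].max() + 1
        with pytest.raises(ValueError, match="odor 0"):
            od.select_state_trials(trials, onset)

    def test_stabilization_mode_first_fifteen_unexcluded(self):
        trials, _ = self._trials(n_awake=18)
        onset = trials[trials.state == AWAKE]["odor_off_s"].max() + 1
        sel = od.select_state_trials(trials, onset, mode="stabilization")
        awake0 = trials[(trials.state == AWAKE) & (trials.odor_id == 0)]
        assert list(sel[0][AWAKE]) == list(awake0.trial_index)[:15]


def test_alignment_stays_near_trial(pcx_features):
    align = pcx_features.alignment
    assert (align["response_inh_s"] >= align["odor_on_s"] - 1e-9).all()
    assert (align["response_inh_s"] <= align["odor_off_s"] + 5.0).all()
    assert (align["baseline_inh_s"] < align["odor_on_s"]).all()
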