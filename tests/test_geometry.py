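"""Pseudopopulation assembly, correlation separation, region nulls,
cross-state correlations, and noise correlations."""

import numpy as np
import pandas as pd
import pytest

import odorstate as od
from odorstate.geometry import noise_correlation_matrix
from odorstate.session import AWAKE, KX


def _labels(odors, trial_idx, state=AWAKE):
    return pd.DataFrame({"odor_id": odors, "trial_idx": trial_idx,
                         "state": state})


class TestBuildPseudopopulation:
    def _session(self, rng, n_cells=5, n_odors=2, n_trials=4):
        odors = np.repeat(np.arange(n_odors), n_trials)
        idx = np.tile(np.arange(n_trials), n_odors)
        X = rng.poisson(4, (odors.size, n_cells)).astype(float)
        return X, _labels(odors, idx)

    def test_single_session_identity(self):
        rng = np.random.default_rng(0)
        X, lab = self._session(rng)
        pop = od.build_pseudopopulation([(X, lab)])
        # rows are sorted by (state, odor, trial index); same grid here
        order = lab.sort_values(["state", "odor_id", "trial_idx"]).index
        np.testing.assert_array_equal(pop.X, X[order])

    def test_cells_pooled_across_sessions(self):
        rng = np.random.default_rng(1)
        s1, s2 = self._session(rng), self._session(rng)
        pop = od.build_pseudopopulation([s1, s2])
        assert pop.X.shape[1] == s1[0].shape[1] + s2[0].shape[1]

    def test_full_subsample_is_permutation(self):
        rng = np.random.default_rng(2)
        X, lab = self._session(rng, n_cells=6)
        pop = od.build_pseudopopulation([(X, lab)], subsample_size=6, seed=0)
        assert sorted(map(tuple, pop.X.T.tolist())) == \
            sorted(map(tuple, X.T.tolist()))

    def test_subsample_deterministic(self):
        rng = np.random.default_rng(3)
        sessions = [self._session(rng), self._session(rng)]
        p1 = od.build_pseudopopulation(sessions, subsample_size=4, seed=9)
        p2 = od.build_pseudopopulation(sessions, subsample_size=4, seed=9)
        np.testing.assert_array_equal(p1.X, p2.X)

    def test_incomplete_session_dropped(self, caplog):
        rng = np.random.default_rng(4)
        full = self._session(rng)
        short_X, short_lab = self._session(rng, n_trials=3)
        pop = od.build_pseudopopulation([full, (short_X, short_lab)])
        assert pop.X.shape[1] == full[0].shape[1]

    def test_oversized_subsample_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            od.build_pseudopopulation([self._session(rng)], subsample_size=99)


class TestCorrelationSeparation:
    def test_orthogonal_patterns_give_two(self):
        a = np.array([1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, 1.0])
        X = np.vstack([a, a, a, b, b, b])
        odors = np.array([0, 0, 0, 1, 1, 1])
        summ = od.correlation_separation(X, odors)
        assert summ.mean_within == pytest.approx(1.0)
        assert summ.mean_across == pytest.approx(-1.0)
        assert summ.separation == pytest.approx(2.0)

    def test_seven_trials_two_odors_bookkeeping(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, (14, 10)).astype(float)
        odors = np.repeat([0, 1], 7)
        summ = od.correlation_separation(X, odors)
        assert summ.n_across_pairs == 49
        assert summ.n_within_pairs == 2 * 21

    def test_hand_computed_toy(self):
        # 3 cells x 2 odors x 2 trials; pairwise Pearson r by hand oracle
        X = np.array([[1.0, 0.0, 1.0],
                      [2.0, 0.0, 1.0],
                      [0.0, 2.0, 0.0],
                      [0.0, 3.0, 1.0]])
        odors = np.array([0, 0, 1, 1])
        def r(u, v):
            return np.corrcoef(u, v)[0, 1]
        within = (r(X[0], X[1]) + r(X[2], X[3])) / 2
        across = (r(X[0], X[2]) + r(X[0], X[3])
                  + r(X[1], X[2]) + r(X[1], X[3])) / 4
        summ = od.correlation_separation(X, odors)
        assert summ.separation == pytest.approx(within - across, abs=1e-12)

    def test_shuffled_labels_center_on_zero(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, (42, 20)).astype(float) \
            + np.repeat(rng.uniform(0, 3, (6, 20)), 7, axis=0)
        seps = []
        for _ in range(500):
            odors = rng.permutation(np.repeat(np.arange(6), 7))
            seps.append(od.correlation_separation(X, odors).separation)
        se = np.std(seps) / np.sqrt(len(seps))
        assert abs(np.mean(seps)) < 3 * se + 1e-3

    def test_invariance_to_common_affine_transform(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(6, (12, 15)).astype(float)
        odors = np.repeat([0, 1, 2], 4)
        s1 = od.correlation_separation(X, odors).separation
        s2 = od.correlation_separation(2.5 * X + 3.0, odors).separation
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_constant_trial_vector_dropped(self):
        X = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0) * 2,
                       5 - np.arange(5.0)])
        odors = np.array([0, 0, 1, 1])
        summ = od.correlation_separation(X, odors)
        assert summ.n_dropped == 3  # all pairs touching the constant row


class TestCrossStateCorrelation:
    def test_identical_states_match_within(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5, (12, 8)).astype(float)
        odors = np.repeat([0, 1, 2], 4)
        cs = od.cross_state_correlation(X, odors, X.copy(), odors)
        ws = od.correlation_separation(X, odors)
        assert cs.separation == pytest.approx(ws.separation, abs=1e-12)

    def test_noise_state_gives_zero(self):
        rng = np.random.default_rng(1)
        odors = np.repeat([0, 1, 2], 5)
        X = rng.poisson(5, (15, 30)).astype(float) \
            + np.repeat(rng.uniform(0, 4, (3, 30)), 5, axis=0)
        noise = rng.poisson(5, (15, 30)).astype(float)
        cs = od.cross_state_correlation(X, odors, noise, odors)
        assert abs(cs.separation) < 0.1

    def test_cell_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cell lists"):
            od.cross_state_correlation(np.zeros((4, 3)), [0, 0, 1, 1],
                                       np.zeros((4, 5)), [0, 0, 1, 1])

    def test_pcx_exceeds_ob_in_simulation(self, small_config):
        from odorstate import pipeline as pl
        seps = {}
        for prof in ("pcx", "ob"):
            b, _ = od.generate_session(small_config, prof, seed=21)
            feats = od.extract_features(b)
            pops = pl._pseudopops([feats], "counts_480")
            cs = od.cross_state_correlation(
                pops[AWAKE].X, pops[AWAKE].odors,
                pops[KX].X, pops[KX].odors)
            seps[prof] = cs.separation
        assert seps["pcx"] > seps["ob"]


class TestSeparationRegionNull:
    def test_null_calibration_and_determinism(self):
        rng = np.random.default_rng(0)
        odors = np.repeat(np.arange(3), 5)
        X = rng.poisson(5, (15, 30)).astype(float) \
            + np.repeat(rng.uniform(0, 2, (3, 30)), 5, axis=0)
        res = od.separation_region_null(X, odors, np.arange(15),
                                        np.arange(15, 30), n_boot=200, seed=1)
        res2 = od.separation_region_null(X, odors, np.arange(15),
                                         np.arange(15, 30), n_boot=200, seed=1)
        assert res["p"] == res2["p"]
        assert res["p"] > 0.05  # same-distribution regions

    def test_detects_planted_region_difference(self):
        rng = np.random.default_rng(2)
        odors = np.repeat(np.arange(3), 7)
        signal = np.repeat(rng.uniform(0, 6, (3, 20)), 7, axis=0)
        strong = rng.poisson(3, (21, 20)) + signal          # tuned region
        weak = rng.poisson(3, (21, 20)).astype(float)       # untuned region
        X = np.hstack([strong, weak])
        res = od.separation_region_null(X, odors, np.arange(20),
                                        np.arange(20, 40), n_boot=200, seed=0)
        assert res["p"] < 0.05
        assert res["separation_a"] > res["separation_b"]


class TestNoiseCorrelations:
    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(0)
        counts = {s: rng.poisson(5.0, (12, 500)) for s in range(6)}
        r, n_pairs = noise_correlation_matrix(counts)
        assert n_pairs == 6 * 66
        assert abs(r) < 0.01

    def test_yoked_cells_give_one(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(5, (1, 100))
        counts = {0: np.vstack([base, base])}
        r, _ = noise_correlation_matrix(counts)
        assert r == pytest.approx(1.0)

    def test_shared_gain_recovers_analytic_value(self):
        # counts ~ Poisson(lam * g), g log-normal with E[g]=1, Var(g)=v:
        # rho = lam^2 v / (lam + lam^2 v) for equal-rate cells
        rng = np.random.default_rng(2)
        lam, sigma = 5.0, 0.2
        v = np.exp(sigma**2) - 1.0
        rho = lam**2 * v / (lam + lam**2 * v)
        counts = {}
        for s in range(6):
            g = rng.lognormal(-sigma**2 / 2, sigma, 500)
            counts[s] = rng.poisson(lam * g, (12, 500))
        r, _ = noise_correlation_matrix(counts)
        assert abs(r - rho) < 0.02

    def test_averaging_order_pairs_then_stimuli(self):
        # constructed so that pair->stimulus order differs from pooling:
        # stimulus 0 has 2 valid cells, stimulus 1 has 3
        rng = np.random.default_rng(3)
        a = rng.standard_normal(50)
        s0 = np.vstack([a, a, np.zeros(50)])          # r=1, 1 pair (3rd const)
        b, c, d = rng.standard_normal((3, 50))
        s1 = np.vstack([b, -b, c])                     # mean r over 3 pairs
        r, _ = noise_correlation_matrix({0: s0, 1: s1})
        r_s1 = np.mean([np.corrcoef(s1[i], s1[j])[0, 1]
                        for i in range(3) for j in range(i + 1, 3)])
        assert r == pytest.approx((1.0 + r_s1) / 2, abs=1e-9)

    def test_sliding_series_shape(self):
        rng = np.random.default_rng(4)
        tensors = {s: rng.poisson(3, (6, 10, 5)) for s in range(2)}
        centers = np.arange(5) * 0.03
        df = od.noise_correlations(tensors, centers, 0.030)
        assert len(df) == 5
        assert np.isfinite(df["mean_r"]).all()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="5 trials"):
            noise_correlation_matrix({0: np.zeros((3, 4))})
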