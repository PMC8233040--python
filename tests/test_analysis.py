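"""Lagged similarity measures, tuning curves and information metrics."""

import numpy as np
import pytest

import hd2speed as h
from hd2speed.analysis import mi_shuffle_bias, permutation_pvalue_spearman


class TestLaggedCorrelation:
    def test_exact_shift_recovered(self, rng):
        x = rng.standard_normal(5000)
        lag_samples = 17
        y = np.roll(x, lag_samples)  # y_t = x_{t-17}, so corr(x_t, y_{t+17})...
        # x_t correlates with y shifted back: x_t == y_{t+17}; with the
        # convention M(x_t, y_{t-l}), the optimum is l = -17
        sim = h.lagged_correlation(x, y, lags=np.arange(-30.0, 31.0), dt=1.0)
        lag, val = h.optimal_lag(sim)
        assert lag == -17.0
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_affine_invariance_at_lag_zero(self, rng):
        x = rng.standard_normal(2000)
        y = 3.0 * x + 2.0
        sim = h.lagged_correlation(x, y, lags=np.array([0.0]), dt=1.0)
        assert sim.values[0] == pytest.approx(1.0)

    def test_white_noise_null(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        sim = h.lagged_correlation(x, y, lags=np.arange(-50.0, 51.0, 2.0), dt=1.0)
        assert np.nanmax(np.abs(sim.values)) < 0.05

    def test_zero_variance_marked_nan(self):
        x = np.ones(500)
        y = np.arange(500.0)
        sim = h.lagged_correlation(x, y, lags=np.array([0.0]), dt=1.0)
        assert np.isnan(sim.values[0])

    def test_non_multiple_lag_rejected(self, rng):
        with pytest.raises(ValueError):
            h.lagged_correlation(rng.random(200), rng.random(200),
                                 lags=np.array([1.5]), dt=1.0)


class TestOptimalLag:
    def test_single_lag(self):
        sim = h.LagSimilarity(lags=np.array([10.0]), values=np.array([0.3]), kind="correlation")
        assert h.optimal_lag(sim) == (10.0, 0.3)

    def test_symmetric_tie_prefers_negative(self):
        sim = h.LagSimilarity(lags=np.array([-20.0, 0.0, 20.0]),
                              values=np.array([0.5, 0.1, 0.5]), kind="correlation")
        assert h.optimal_lag(sim)[0] == -20.0

    def test_matches_exhaustive_scan(self, rng):
        vals = rng.random(71)
        sim = h.LagSimilarity(lags=np.arange(-70.0, 71.0, 2.0), values=vals, kind="correlation")
        lag, val = h.optimal_lag(sim)
        assert val == vals.max()
        assert sim.lags[np.argmax(vals)] == lag or val == pytest.approx(vals.max())

    def test_all_nan_raises(self):
        sim = h.LagSimilarity(lags=np.array([0.0, 2.0]),
                              values=np.array([np.nan, np.nan]), kind="correlation")
        with pytest.raises(ValueError):
            h.optimal_lag(sim)


class TestMutualInformation:
    def test_self_information_is_entropy(self, rng):
        x = rng.standard_normal(50_000)
        mi = h.mutual_information(x, x, bins=40)
        counts, _ = np.histogram(x, bins=40)
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mi == pytest.approx(entropy, rel=1e-9)

    def test_independent_pair_within_plugin_bias(self, rng):
        n = 50_000
        x, y = rng.standard_normal((2, n))
        mi = h.mutual_information(x, y, bins=40)
        analytic_bias = (40 - 1) ** 2 / (2 * n * np.log(2))
        shuffle_bias = mi_shuffle_bias(x, y, 40, 20, seed=0)
        assert mi < 3 * analytic_bias
        assert shuffle_bias == pytest.approx(analytic_bias, rel=0.3)

    def test_symmetry_and_nonnegativity(self, rng):
        x = rng.standard_normal(5000)
        y = x + rng.standard_normal(5000)
        assert h.mutual_information(x, y) == pytest.approx(h.mutual_information(y, x), rel=1e-9)
        assert h.mutual_information(x, y) >= 0.0

    def test_lagged_mi_tracks_shift(self, rng):
        x = np.convolve(rng.standard_normal(8000), np.ones(20) / 20, mode="same")
        y = np.roll(x, 10)
        sim = h.lagged_mutual_information(x, y, lags=np.arange(-20.0, 21.0, 2.0), dt=1.0)
        assert h.optimal_lag(sim)[0] == -10.0


class TestSpeedTuning:
    def test_flat_for_independent_rate(self, rng):
        rate = rng.normal(30.0, 1.0, 50_000)
        speed = np.abs(rng.standard_normal(50_000))
        st = h.speed_tuning_curve(rate, speed, n_bins=8)
        good = st.counts > 100
        assert np.all(np.abs(st.mean_rate[good] - 30.0) < 0.5)

    def test_quadratic_relation_recovered(self, rng):
        speed = np.abs(rng.standard_normal(20_000)) + 0.05
        rate = 3.0 * speed**2
        st = h.speed_tuning_curve(rate, speed, n_bins=10)
        good = st.counts > 50
        slope = np.polyfit(np.log(st.bin_centers[good]), np.log(st.mean_rate[good]), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_symmetric_code_symmetric_curve(self, rng):
        omega = rng.standard_normal(100_000)
        rate = 10.0 + omega**2
        edges = np.linspace(-3.0, 3.0, 13)
        st = h.speed_tuning_curve(rate, omega, bin_edges=edges)
        nb = len(st.mean_rate)
        for b in range(nb // 2):
            if st.counts[b] > 200 and st.counts[nb - 1 - b] > 200:
                assert st.mean_rate[b] == pytest.approx(st.mean_rate[nb - 1 - b], rel=0.05)


class TestActiveWindowCorrelation:
    def test_constant_cell_excluded(self):
        speed = np.linspace(0, 5, 1000)
        vals, excl = h.active_window_correlation([np.full(1000, 20.0)], speed)
        assert len(vals) == 0 and excl == 1

    def test_positive_control(self):
        speed = np.abs(np.sin(np.linspace(0, 30, 5000))) * 30 + 1
        vals, _ = h.active_window_correlation([speed.copy()], speed, threshold=10.0)
        assert vals[0] == pytest.approx(1.0)

    def test_subthreshold_cell_excluded(self):
        speed = np.linspace(0, 5, 1000)
        vals, excl = h.active_window_correlation([np.full(1000, 1.0)], speed, threshold=10.0)
        assert len(vals) == 0 and excl == 1


class TestDirectionInformation:
    def test_independent_rate_low_mi(self, rng):
        rate = rng.standard_normal(50_000)
        theta = rng.uniform(0, 2 * np.pi, 50_000)
        mi, _ = h.direction_information(rate, theta)
        bias = (40 - 1) ** 2 / (2 * 50_000 * np.log(2))
        assert mi < 3 * bias

    def test_deterministic_tuning_high_scores(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 50_000)
        rate = 10.0 + 4.0 * np.cos(theta - 1.0)  # cosine tuning: exactly linear in (cos, sin)
        mi, circ = h.direction_information(rate, theta)
        assert circ == pytest.approx(1.0, abs=1e-6)
        assert mi > 1.0

    def test_rotation_invariance_of_mi(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 20_000)
        rate = np.exp(np.cos(theta)) + rng.normal(0, 0.1, 20_000)
        mi1, _ = h.direction_information(rate, theta)
        mi2, _ = h.direction_information(rate, np.mod(theta + 1.23, 2 * np.pi))
        # rotation permutes direction bins; plug-in MI changes only through
        # bin-edge placement
        assert mi1 == pytest.approx(mi2, rel=0.05)


class TestPermutationSpearman:
    def test_monotone_association_significant(self, rng):
        a = rng.random(60)
        b = a + rng.normal(0, 0.1, 60)
        rho, p = permutation_pvalue_spearman(a, b, n_perm=500, seed=0)
        assert rho > 0.8 and p < 0.01

    def test_null_not_significant(self, rng):
        a, b = rng.random((2, 60))
        _, p = permutation_pvalue_spearman(a, b, n_perm=500, seed=1)
        assert p > 0.05
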