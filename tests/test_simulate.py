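"""Stochastic maturation under a fluctuating rate constant."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import fpmat as fm
from fpmat.simulate import RATE_FLOOR, RateSeries, half_time_floor_stats

LN2 = math.log(2.0)


class TestRateSeries:
    def test_zero_sigma_is_constant(self):
        s = fm.make_rate_series(0.1, 0.0, lag=0.5, horizon=10, seed=0)
        assert np.all(s.values == 0.1)

    def test_seed_determinism(self):
        a = fm.make_rate_series(0.1, 0.05, lag=0.5, horizon=50, seed=3)
        b = fm.make_rate_series(0.1, 0.05, lag=0.5, horizon=50, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_sample_mean_within_monte_carlo_error(self):
        mean_k = 0.0231
        s = fm.make_rate_series(mean_k, 0.5 * mean_k, lag=1.0, horizon=1e5,
                                seed=1)
        se = s.values.std(ddof=1) / math.sqrt(s.values.size)
        assert abs(s.values.mean() - mean_k) < 3 * se

    def test_values_clamped_at_floor(self):
        s = fm.make_rate_series(0.01, 1.0, lag=1.0, horizon=1000, seed=2)
        assert s.values.min() >= RATE_FLOOR
        assert s.n_clamped() > 0

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            fm.make_rate_series(0.1, 0.0, lag=0.5, horizon=0.0)


class TestWindowAverage:
    def test_hand_integrated_window(self):
        s = RateSeries(lag=1.0, values=np.array([1.0, 2.0, 3.0]),
                       mean_k=2.0, sigma=0.0)
        assert fm.window_average(s, 0.5, 2.5) == pytest.approx(2.0)

    def test_constant_series_any_window(self):
        s = RateSeries(lag=1.0, values=np.full(10, 0.7), mean_k=0.7, sigma=0.0)
        assert fm.window_average(s, 0.3, 7.9) == pytest.approx(0.7)

    def test_window_inside_one_cell(self):
        s = RateSeries(lag=1.0, values=np.array([1.0, 2.0, 3.0]),
                       mean_k=2.0, sigma=0.0)
        assert fm.window_average(s, 1.2, 1.8) == pytest.approx(2.0)

    def test_window_beyond_horizon_not_extendable(self):
        s = RateSeries(lag=1.0, values=np.ones(3), mean_k=1.0, sigma=0.0)
        with pytest.raises(RuntimeError):
            fm.window_average(s, 0.0, 10.0)

    def test_invalid_window_rejected(self):
        s = RateSeries(lag=1.0, values=np.ones(3), mean_k=1.0, sigma=0.0)
        with pytest.raises(ValueError):
            fm.window_average(s, 2.0, 1.0)


def constant_series(k, lag=0.1, horizon=5000.0):
    n = int(horizon / lag)
    return RateSeries(lag=lag, values=np.full(n, k), mean_k=k, sigma=0.0)


class TestSimulateCell:
    @pytest.mark.parametrize("scheme", ["averaged", "exact"])
    def test_single_molecule_constant_rate_is_exponential(self, scheme):
        k = 0.05
        rng = np.random.default_rng(0)
        times = [fm.simulate_cell(constant_series(k), 1, scheme=scheme, rng=rng)
                 for _ in range(1500)]
        assert sps.kstest(times, "expon", args=(0, 1 / k)).pvalue > 0.01

    def test_order_statistic_closed_form(self):
        k = 0.0231
        n_mol, n_cells = 200, 600
        rng = np.random.default_rng(1)
        ht = np.array([fm.simulate_cell(constant_series(k), n_mol,
                                        scheme="exact", rng=rng)
                       for _ in range(n_cells)])
        mean_th, cv_th = half_time_floor_stats(n_mol, k)
        se = ht.std(ddof=1) / math.sqrt(n_cells)
        assert abs(ht.mean() - mean_th) < 3.5 * se
        assert fm.cv(ht) == pytest.approx(cv_th, rel=0.15)

    def test_schemes_agree_on_constant_rate(self):
        k = 0.05
        rng = np.random.default_rng(2)
        a = [fm.simulate_cell(constant_series(k), 100, scheme="averaged", rng=rng)
             for _ in range(600)]
        b = [fm.simulate_cell(constant_series(k), 100, scheme="exact", rng=rng)
             for _ in range(600)]
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_exact_matches_thinning_oracle_on_fluctuating_rate(self):
        # independent construction: propose events at the ceiling rate and
        # accept with probability k(t)/k_max (Lewis-Shedler thinning)
        mean_k, sigma, lag = 0.05, 0.025, 0.5
        n_mol, n_cells = 8, 500

        def thinning_half_time(series, rng):
            k_max = series.values.max()
            done = []
            for _ in range(n_mol):
                t = 0.0
                while True:
                    t += rng.exponential(1.0 / k_max)
                    if rng.random() < series.value_at(t) / k_max:
                        break
                done.append(t)
            done.sort()
            return done[(n_mol + 1) // 2 - 1]

        rng = np.random.default_rng(3)
        mine, oracle = [], []
        for _ in range(n_cells):
            s1 = fm.make_rate_series(mean_k, sigma, lag, horizon=2000, rng=rng)
            mine.append(fm.simulate_cell(s1, n_mol, scheme="exact", rng=rng))
            s2 = fm.make_rate_series(mean_k, sigma, lag, horizon=2000, rng=rng)
            oracle.append(thinning_half_time(s2, rng))
        assert sps.ks_2samp(mine, oracle).pvalue > 0.01

    def test_exact_invariant_to_grid_refinement_of_fixed_path(self):
        values = np.random.default_rng(4).uniform(0.02, 0.08, 50)
        coarse = RateSeries(lag=2.0, values=values, mean_k=0.05, sigma=0.0)
        fine = RateSeries(lag=0.5, values=np.repeat(values, 4),
                          mean_k=0.05, sigma=0.0)
        a = fm.simulate_cell(coarse, 64, scheme="exact", seed=9)
        b = fm.simulate_cell(fine, 64, scheme="exact", seed=9)
        assert a == pytest.approx(b, rel=1e-12)

    def test_one_pass_averaging_mode_runs(self):
        rng = np.random.default_rng(5)
        s = fm.make_rate_series(0.05, 0.01, 0.5, horizon=2000, rng=rng)
        t = fm.simulate_cell(s, 50, scheme="averaged", rng=rng,
                             averaging="one_pass")
        assert t > 0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            fm.simulate_cell(constant_series(0.1), 10, scheme="magic")


class TestRunConditionAndSweep:
    def test_defaults_match_study_conditions(self):
        cfg = fm.SimConfig()
        assert cfg.n_cells == 100 and cfg.n_molecules == 2000

    def test_zero_sigma_cv_independent_of_lag(self):
        a = fm.run_condition(fm.SimConfig(n_cells=40, n_molecules=200,
                                          sigma_rel=0.0, lag=0.1, seed=6,
                                          bootstrap_B=100))
        b = fm.run_condition(fm.SimConfig(n_cells=40, n_molecules=200,
                                          sigma_rel=0.0, lag=1.0, seed=6,
                                          bootstrap_B=100))
        assert a.cv == pytest.approx(b.cv, rel=1e-12)

    def test_constant_rate_mean_recovers_maturation_time(self):
        res = fm.run_condition(fm.SimConfig(n_cells=60, n_molecules=500,
                                            mean_mat_time=30.0, sigma_rel=0.0,
                                            seed=7, bootstrap_B=100))
        assert res.mean_half_time == pytest.approx(30.0, rel=0.02)

    def test_sweep_is_deterministic_and_tidy(self):
        base = fm.SimConfig(n_cells=10, n_molecules=50, seed=8, bootstrap_B=100)
        a = fm.sweep(base, "sigma", [0.0, 0.5])
        b = fm.sweep(base, "sigma", [0.0, 0.5])
        assert a.equals(b)
        assert list(a.columns) == ["axis", "value", "mean_half_time", "cv",
                                   "cv_lo", "cv_hi", "n_cells", "n_clamped"]

    def test_sweep_value_list_validated(self):
        base = fm.SimConfig(n_cells=5, n_molecules=20, bootstrap_B=100)
        with pytest.raises(ValueError):
            fm.sweep(base, "sigma", [0.5])
        with pytest.raises(ValueError):
            fm.sweep(base, "volume", [1, 2])

    def test_large_lag_warns(self):
        with pytest.warns(UserWarning, match="much shorter"):
            fm.SimConfig(mean_mat_time=10.0, lag=5.0)
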