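"""Analytic kinetics and per-cell maturation-rate inference."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import fpmat as fm
from fpmat.kinetics import LN2, FitOptions, traces_to_frame


def numerical_curves(params, times):
    """Independent oracle: adaptive integration of the kinetic ODE system
    (mRNA production/turnover, translation, first-order maturation)."""

    def rhs(t, y):
        m, p, fi = y
        return [params.k - params.alpha * m, m, params.k3 * (p - fi)]

    sol = solve_ivp(rhs, (0.0, float(max(times))), [0.0, 0.0, 0.0],
                    t_eval=times, rtol=1e-11, atol=1e-13, method="LSODA")
    return sol.y[1], sol.y[2]


class TestAnalyticCurves:
    def test_initial_conditions_zero(self):
        p = fm.KineticParams(k=2.0, k3=0.05)
        c = fm.analytic_curves(p, [0.0])
        assert c.m[0] == 0 and c.p_total[0] == 0 and c.fi[0] == 0

    @pytest.mark.parametrize("k3", [1e-3, 0.0299, 0.03, 0.0301, 0.1, 0.5])
    def test_matches_numerical_integration(self, k3):
        p = fm.KineticParams(k=1.0, k3=k3, alpha=0.03)
        times = np.array([10.0, 60.0, 240.0])
        c = fm.analytic_curves(p, times)
        p_num, fi_num = numerical_curves(p, times)
        assert np.allclose(c.fi, fi_num, rtol=1e-8)
        assert np.allclose(c.p_total, p_num, rtol=1e-8)

    def test_instantaneous_maturation_limit(self):
        # very fast maturation: the matured signal tracks total protein.
        # The unmatured backlog is ~ (dP/dt)/k3, so the relative gap decays
        # like 2/(k3*t); at k3 = 1e3/min it is below 0.1% once t > ~2 min.
        p = fm.KineticParams(k=3.0, k3=1e3, alpha=0.03)
        t = np.linspace(3.0, 360, 200)
        c = fm.analytic_curves(p, t)
        assert np.all(np.abs(c.fi - c.p_total) <= 1e-3 * c.p_total)

    @given(
        k=st.floats(0.01, 100.0),
        k3=st.floats(1e-4, 2.0),
        alpha=st.floats(1e-3, 0.3),
    )
    def test_matured_fraction_bounded(self, k, k3, alpha):
        p = fm.KineticParams(k=k, k3=k3, alpha=alpha)
        c = fm.analytic_curves(p, np.linspace(0, 500, 60))
        assert np.all(c.fi >= 0)
        assert np.all(c.fi <= c.p_total + 1e-9 * np.abs(c.p_total))
        assert np.allclose(c.i_unmatured, c.p_total - c.fi)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            fm.analytic_curves(fm.KineticParams(k=1, k3=0.1), [-1.0, 2.0])


class TestMaturationTime:
    def test_known_values(self):
        assert fm.maturation_time(LN2 / 10.0) == pytest.approx(10.0)
        assert fm.maturation_time(LN2 / 140.0) == pytest.approx(140.0)

    @given(st.floats(0.1, 500.0))
    def test_inverse_identity(self, x):
        assert fm.maturation_time(LN2 / x) == pytest.approx(x, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fm.maturation_time(0.0)


class TestSubtractBackground:
    def test_constant_trace_goes_to_zero(self):
        tr = fm.CellTrace(0, np.arange(5.0), np.full(5, 7.0), np.full(5, 7.0))
        out = fm.subtract_background(tr, 3)
        assert np.allclose(out.fc, 0) and np.allclose(out.fi, 0)

    def test_idempotent_on_zero_baseline(self):
        cfg = fm.TraceGenConfig(n_cells=1, cv_k=0, cv_mat_time=0,
                                meas_noise_cv=0, n_preinduction_frames=3, seed=0)
        tr = fm.generate_trace_set(cfg)[0]
        once = fm.subtract_background(tr, 3)
        twice = fm.subtract_background(once, 3)
        assert np.allclose(once.fc, twice.fc) and np.allclose(once.fi, twice.fi)

    def test_recovers_synthetic_offset(self):
        cfg = fm.TraceGenConfig(n_cells=1, bg_fc=50.0, bg_fi=20.0,
                                meas_noise_cv=0.01, n_preinduction_frames=5, seed=2)
        tr = fm.generate_trace_set(cfg)[0]
        out = fm.subtract_background(tr, 5)
        assert abs(out.fc[:5].mean()) < 1e-9
        assert abs(out.fi[:5].mean()) < 1e-9

    def test_too_short_trace_rejected(self):
        tr = fm.CellTrace(0, np.arange(3.0), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            fm.subtract_background(tr, 3)


class TestScalingRatio:
    def _experiment(self, r, noise, n_cells=50, seed=0):
        cfg = fm.ScalingConfig(n_cells=n_cells, scaling_ratio_R=r,
                               meas_noise_cv=noise, seed=seed)
        return fm.generate_scaling_experiment(cfg), cfg

    def test_identical_channels_give_unity(self):
        df, cfg = self._experiment(1.0, 0.0)
        df["fi"] = df["fc"]
        est = fm.estimate_scaling_ratio(df, (0, 30), (450, 600))
        assert est.r == pytest.approx(1.0)

    def test_round_trip_recovery(self):
        df, _ = self._experiment(0.37, 0.02)
        est = fm.estimate_scaling_ratio(df, (0, 30), (450, 600))
        assert est.r == pytest.approx(0.37, rel=0.05)
        assert est.n_excluded == 0

    def test_zero_expression_is_error(self):
        cfg = fm.ScalingConfig(n_cells=10, mean_ss_level=0.0, meas_noise_cv=0.0)
        df = fm.generate_scaling_experiment(cfg)
        with pytest.raises(ValueError, match="non-positive"):
            fm.estimate_scaling_ratio(df, (0, 30), (450, 600))

    def test_overlapping_windows_rejected(self):
        df, _ = self._experiment(0.5, 0.0)
        with pytest.raises(ValueError, match="overlap"):
            fm.estimate_scaling_ratio(df, (0, 100), (50, 600))


def make_clean_trace(k=5.0, k3=0.02, alpha=0.03, R=0.5, cell_id=0):
    params = fm.KineticParams(k=k, k3=k3, alpha=alpha, R=R)
    t = np.arange(0.0, 361.0, 6.0)
    c = fm.analytic_curves(params, t)
    return fm.CellTrace(cell_id, t, c.p_total / R, c.fi, true_params=params)


class TestFitCell:
    @pytest.mark.parametrize("k3", [1e-3, 5e-3, 0.0299999, 0.03, 0.0300001,
                                    0.1, 0.5])
    def test_noise_free_round_trip(self, k3):
        tr = make_clean_trace(k3=k3)
        fit = fm.fit_cell(tr, R=0.5, alpha=0.03)
        assert fit.status == "ok"
        assert fit.k3_hat == pytest.approx(k3, rel=1e-6)
        assert fit.k_hat == pytest.approx(5.0, rel=1e-9)
        assert fit.r2_fi > 1 - 1e-10

    def test_joint_refinement_matches_two_stage_noise_free(self):
        tr = make_clean_trace(k3=0.05)
        plain = fm.fit_cell(tr, R=0.5, alpha=0.03)
        joint = fm.fit_cell(tr, R=0.5, alpha=0.03,
                            options=FitOptions(joint_refine=True))
        assert joint.k3_hat == pytest.approx(plain.k3_hat, rel=1e-6)

    def test_unit_invariance(self):
        # rescaling both channels (same gain) leaves k3 unchanged
        tr = make_clean_trace(k3=0.04)
        scaled = fm.CellTrace(0, tr.times, 37.0 * tr.fc, 37.0 * tr.fi)
        a = fm.fit_cell(tr, R=0.5)
        b = fm.fit_cell(scaled, R=0.5)
        assert b.k3_hat == pytest.approx(a.k3_hat, rel=1e-9)
        assert b.k_hat == pytest.approx(37.0 * a.k_hat, rel=1e-9)

    def test_heavy_noise_fails_qc(self):
        tr = make_clean_trace(k3=0.02)
        noisy_fi = tr.fi * np.random.default_rng(0).lognormal(0, 0.8, tr.fi.shape)
        fit = fm.fit_cell(fm.CellTrace(0, tr.times, tr.fc, noisy_fi), R=0.5)
        assert not fit.qc_pass

    def test_qc_threshold_default(self):
        assert FitOptions().r2_threshold == 0.98

    def test_short_window_rejected(self):
        tr = make_clean_trace()
        with pytest.raises(ValueError, match="6 frames"):
            fm.fit_cell(fm.CellTrace(0, tr.times[:4], tr.fc[:4], tr.fi[:4]), R=0.5)

    def test_constant_signal_is_degenerate(self):
        t = np.arange(0.0, 61.0, 6.0)
        fit = fm.fit_cell(fm.CellTrace(0, t, np.ones_like(t), np.ones_like(t)),
                          R=0.5)
        assert fit.status == "degenerate" and not fit.qc_pass


class TestFitTraceSet:
    def test_clean_cells_all_pass_no_outliers(self):
        cfg = fm.TraceGenConfig(n_cells=20, meas_noise_cv=0.0, cv_k=0,
                                cv_mat_time=0, seed=3)
        df = fm.fit_trace_set(fm.generate_trace_set(cfg), R=0.5)
        assert df["qc_pass"].all()
        assert not df["outlier"].any()

    def test_planted_slow_cell_is_the_only_outlier(self):
        # ordinary cells need some spread, else the MAD degenerates to zero
        k3s = 0.05 * np.linspace(0.9, 1.1, 19)
        traces = [make_clean_trace(k3=k3, cell_id=i) for i, k3 in enumerate(k3s)]
        traces.append(make_clean_trace(k3=0.005, cell_id=99))
        df = fm.fit_trace_set(traces, R=0.5)
        flagged = df.loc[df["outlier"], "cell_id"].tolist()
        assert flagged == [99]

    def test_no_silent_row_drops(self):
        traces = [make_clean_trace(cell_id=i) for i in range(5)]
        df = fm.fit_trace_set(traces, R=0.5)
        assert len(df) == 5

    def test_all_qc_failures_raise(self):
        t = np.arange(0.0, 61.0, 6.0)
        flat = [fm.CellTrace(i, t, np.ones_like(t), np.ones_like(t))
                for i in range(4)]
        with pytest.raises(ValueError, match="no cell passed QC"):
            fm.fit_trace_set(flat, R=0.5)

    def test_traces_to_frame_is_tidy(self):
        traces = [make_clean_trace(cell_id=i) for i in range(3)]
        df = traces_to_frame(traces)
        assert set(df.columns) == {"cell_id", "time_min", "fc", "fi"}
        assert df["cell_id"].nunique() == 3
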