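"""Forward 2TCM solution, joint-delay fitting, and macro-parameters."""

import numpy as np
import pytest

import petkin as pk
from petkin.curves import TimeActivityCurve
from petkin.kinetics import FitOptions, _ForwardModel


class TestSolve2TCM:
    def test_no_uptake_reduces_to_blood(self, default_ifs, schedule):
        """With K1 = 0 the signal is pure blood volume: vb * C_wb."""
        p = pk.TwoTissueParams(vb=0.05, K1=0.0, k2=0.1, k3=0.1, k4=0.1, delay=0.0)
        model = pk.solve_2tcm(p, default_ifs, schedule)
        # independent frame-averaging of the interpolated whole-blood curve
        expected = np.empty(schedule.n_frames)
        for i in range(schedule.n_frames):
            tt = np.linspace(schedule.starts[i], schedule.ends[i], 601)
            vals = pk.interpolate_curve(default_ifs.whole_blood, tt)
            expected[i] = 0.05 * np.trapezoid(vals, tt) / schedule.durations[i]
        np.testing.assert_allclose(model.values, expected, rtol=1e-4)

    def test_one_tissue_collapse(self, default_ifs, schedule):
        """vb = 0, k3 = 0: C_T = K1 e^{-k2 t} (x) C_p, checked against a direct
        discrete convolution."""
        p = pk.TwoTissueParams(vb=0.0, K1=0.3, k2=0.2, k3=0.0, k4=0.0, delay=0.0)
        model = pk.solve_2tcm(p, default_ifs, schedule)
        t_s = np.arange(0.0, schedule.total_seconds + 0.5, 0.5)
        t_min = t_s / 60.0
        dt = t_min[1] - t_min[0]
        cp = pk.interpolate_curve(default_ifs.parent_plasma, t_s)
        h = 0.3 * np.exp(-0.2 * t_min)
        conv = np.convolve(cp, h)[: t_s.size] * dt
        conv -= 0.5 * dt * (cp * h[0] + cp[0] * h)
        expected = np.empty(schedule.n_frames)
        for i in range(schedule.n_frames):
            sel = (t_s >= schedule.starts[i]) & (t_s <= schedule.ends[i])
            expected[i] = np.trapezoid(conv[sel], t_s[sel]) / schedule.durations[i]
        # normalized by the curve maximum: early bolus-edge frames are near 0
        assert np.max(np.abs(model.values - expected)) / expected.max() < 2e-3

    def test_repeated_root_degenerate(self, default_ifs, schedule):
        """k2 = k4, k3 = 0 makes theta1 = theta2; the closed form must stay finite
        and agree with a slightly perturbed (distinct-root) parameter set."""
        p_eq = pk.TwoTissueParams(vb=0.02, K1=0.3, k2=0.1, k3=0.0, k4=0.1, delay=0.0)
        p_near = pk.TwoTissueParams(vb=0.02, K1=0.3, k2=0.1, k3=1e-7, k4=0.1, delay=0.0)
        a = pk.solve_2tcm(p_eq, default_ifs, schedule)
        b = pk.solve_2tcm(p_near, default_ifs, schedule)
        assert np.all(np.isfinite(a.values))
        assert np.max(np.abs(a.values - b.values)) / b.values.max() < 1e-5


class TestFit2TCM:
    @pytest.mark.parametrize("weighting", ["duration", "uniform"])
    def test_noiseless_recovery(self, default_ifs, schedule, weighting):
        truth = pk.TwoTissueParams(vb=0.035, K1=0.30, k2=0.20, k3=0.03, k4=0.07, delay=5.0)
        tac = pk.solve_2tcm(truth, default_ifs, schedule)
        fit = pk.fit_2tcm(tac, default_ifs, FitOptions(weighting=weighting))
        assert fit.converged
        for name in ("vb", "K1", "k2", "k3", "k4"):
            got, want = getattr(fit.params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=0.01), name
        assert abs(fit.params.delay - truth.delay) < 0.5

    def test_pure_blood_signal(self, default_ifs, schedule):
        """Data equal to vb*C_wb: K1 is driven to its lower bound, vb recovered."""
        truth = pk.TwoTissueParams(vb=0.04, K1=0.0, k2=0.1, k3=0.1, k4=0.1, delay=0.0)
        tac = pk.solve_2tcm(truth, default_ifs, schedule)
        fit = pk.fit_2tcm(tac, default_ifs)
        assert fit.params.K1 < 1e-4
        assert fit.params.vb == pytest.approx(0.04, rel=0.01)

    def test_truncation_at_full_length_is_identity(self, mt_tac, default_ifs):
        full = pk.fit_2tcm(mt_tac, default_ifs)
        trunc = pk.fit_2tcm(pk.truncate_to_duration(mt_tac, 90.0), default_ifs)
        assert full.params == trunc.params
        assert full.residual_sumsq == trunc.residual_sumsq

    def test_input_scaling_covariance(self, mt_truth, mt_tac, default_ifs):
        """Multiplying the input set and the data by c leaves rate constants,
        vb, delay and V_T unchanged."""
        c = 2.0
        scaled_wb = default_ifs.whole_blood.with_values(default_ifs.whole_blood.values * c)
        scaled_ifs = pk.build_input_set(
            scaled_wb, default_ifs.parent_model, default_ifs.ratio_model
        )
        scaled_tac = mt_tac.with_values(mt_tac.values * c)
        fit = pk.fit_2tcm(scaled_tac, scaled_ifs)
        for name in ("vb", "K1", "k2", "k3", "k4"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(mt_truth, name), rel=0.01
            ), name
        assert fit.vt == pytest.approx(pk.compute_vt(mt_truth), rel=0.01)

    def test_non_finite_tac_rejected(self, schedule, default_ifs):
        vals = np.ones(schedule.n_frames)
        with pytest.raises(ValueError):
            TimeActivityCurve(schedule, np.where(np.arange(65) == 3, np.nan, vals), "x")

    def test_grid_step_convergence(self, mt_truth, default_ifs, schedule):
        coarse = pk.solve_2tcm(mt_truth, default_ifs, schedule, grid_step=1.0)
        fine = pk.solve_2tcm(mt_truth, default_ifs, schedule, grid_step=0.25)
        # discretization error concentrates in the steep 2-s bolus frames
        assert np.max(np.abs(coarse.values - fine.values)) / fine.values.max() < 5e-3
        late = slice(42, None)  # 60-s and 300-s frames
        np.testing.assert_allclose(coarse.values[late], fine.values[late], rtol=1e-3)


class TestMacroParameters:
    def test_vt_at_cohort_means(self):
        # K1/k2 (1 + k3/k4) at the lateral-parietal cohort means
        p = pk.TwoTissueParams(vb=0.029, K1=0.372, k2=0.245, k3=0.031, k4=0.083, delay=0)
        assert pk.compute_vt(p) == pytest.approx(2.08546, abs=1e-4)

    def test_vt_special_cases(self):
        p = pk.TwoTissueParams(vb=0.0, K1=0.3, k2=0.15, k3=0.0, k4=0.1, delay=0)
        assert pk.compute_vt(p) == pytest.approx(0.3 / 0.15)
        p2 = pk.TwoTissueParams(vb=0.0, K1=0.2, k2=0.2, k3=0.05, k4=0.05, delay=0)
        assert pk.compute_vt(p2) == pytest.approx(2.0)

    def test_vt_undefined(self):
        p = pk.TwoTissueParams(vb=0.0, K1=0.3, k2=0.0, k3=0.0, k4=0.1, delay=0)
        with pytest.raises(ValueError):
            pk.compute_vt(p)

    def test_vt_monotonicity(self):
        base = dict(vb=0.03, K1=0.3, k2=0.2, k3=0.03, k4=0.07, delay=0.0)
        vt0 = pk.compute_vt(pk.TwoTissueParams(**base))
        up = lambda **kw: pk.compute_vt(pk.TwoTissueParams(**{**base, **kw}))
        assert up(K1=0.35) > vt0 and up(k3=0.04) > vt0
        assert up(k2=0.25) < vt0 and up(k4=0.09) < vt0

    def test_vt_time_unit_invariance(self):
        # rescaling all rate constants by the same factor (a change of time
        # unit) leaves V_T unchanged
        p = pk.TwoTissueParams(vb=0.0, K1=0.3, k2=0.2, k3=0.03, k4=0.07, delay=0)
        c = 1.0 / 60.0
        q = pk.TwoTissueParams(vb=0.0, K1=0.3 * c, k2=0.2 * c, k3=0.03 * c, k4=0.07 * c, delay=0)
        assert pk.compute_vt(p) == pytest.approx(pk.compute_vt(q))

    def test_dvr(self):
        assert pk.compute_dvr(2.0, 2.0) == 1.0
        assert pk.compute_dvr(4.0, 2.0) == 2.0
        with pytest.raises(ValueError):
            pk.compute_dvr(2.0, 0.0)

    def test_dvr_cohort_consistency(self):
        """The cohort's V_T/DVR ratios imply one common reference V_T ~ 2.04."""
        ratios = [2.111 / 1.035, 2.159 / 1.057, 2.081 / 1.022]
        assert all(abs(r - 2.04) < 0.01 for r in ratios)
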