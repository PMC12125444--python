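"""Plasma/metabolite correction, delay shifting and peak perturbation."""

import numpy as np
import pytest

import petkin as pk
from petkin.curves import TimeActivityCurve
from petkin.input_function import peak_window
from petkin.synthetic import InputModel, generate_input


def make_tac(spec, values, label="wb"):
    return TimeActivityCurve(pk.parse_frame_schedule(spec), np.asarray(values, float), label)


class TestParentFraction:
    def test_equals_100_at_t0(self):
        m = pk.ParentFractionModel(alpha=37.0, tau1=4.0, tau2=90.0, t0=1.5)
        assert pk.parent_fraction(1.5, m) == pytest.approx(100.0)

    def test_collapses_to_single_exponential(self):
        # alpha=50, tau1=tau2=10 min, t0=0: p(10) = 100 e^-1
        m = pk.ParentFractionModel(alpha=50.0, tau1=10.0, tau2=10.0, t0=0.0)
        assert pk.parent_fraction(10.0, m) == pytest.approx(100.0 * np.exp(-1), rel=1e-12)

    def test_limits_and_clamp(self):
        m = pk.ParentFractionModel(alpha=55.0, tau1=6.0, tau2=120.0, t0=1.0)
        assert pk.parent_fraction(1e6, m) == pytest.approx(0.0, abs=1e-12)
        assert pk.parent_fraction(0.0, m) == 100.0  # before t0: no metabolism

    def test_continuous_and_non_increasing(self):
        m = pk.ParentFractionModel(alpha=55.0, tau1=6.0, tau2=120.0, t0=1.0)
        t = np.linspace(0.0, 90.0, 2001)
        p = pk.parent_fraction(t, m)
        assert np.all(np.diff(p) <= 1e-12)
        eps = 1e-9
        assert pk.parent_fraction(m.t0 + eps, m) == pytest.approx(100.0, abs=1e-6)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            pk.ParentFractionModel(alpha=50.0, tau1=-1.0, tau2=10.0)
        with pytest.raises(ValueError):
            pk.ParentFractionModel(alpha=120.0, tau1=1.0, tau2=10.0)


class TestPlasmaCorrection:
    def test_unity_ratio_is_identity(self):
        wb = make_tac("3x60", [2.0, 4.0, 6.0])
        out = pk.apply_plasma_correction(wb, pk.PlasmaRatioModel.constant(1.0))
        np.testing.assert_allclose(out.values, wb.values)

    def test_constant_ratio(self):
        wb = make_tac("1x60", [4.0])
        out = pk.apply_plasma_correction(wb, pk.PlasmaRatioModel.constant(1.25))
        assert out.values[0] == pytest.approx(5.0)

    def test_time_varying_ratio(self):
        # ratio 1.0 at 0 min, 1.2 at 90 min; frame mid at 45 min -> ratio 1.1
        wb = make_tac("1x5400", [10.0])
        ratio = pk.PlasmaRatioModel(times=[0.0, 90.0], ratios=[1.0, 1.2])
        out = pk.apply_plasma_correction(wb, ratio)
        assert out.values[0] == pytest.approx(11.0)

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            pk.PlasmaRatioModel(times=[0.0, 1.0], ratios=[1.0, 0.0])
        with pytest.raises(ValueError):
            pk.PlasmaRatioModel(times=[1.0, 1.0], ratios=[1.0, 1.1])


class TestMetaboliteCorrection:
    def test_no_metabolism_is_identity(self):
        plasma = make_tac("3x60", [1.0, 2.0, 3.0])
        m = pk.ParentFractionModel(alpha=100.0, tau1=1e9, tau2=1e9, t0=0.0)
        out = pk.apply_metabolite_correction(plasma, m)
        np.testing.assert_allclose(out.values, plasma.values, rtol=1e-7)

    def test_known_fraction(self):
        # frame mid at 10 min where p = 100 e^-1 = 36.788%: 10 -> 3.6788
        plasma = make_tac("1x1200", [10.0])
        m = pk.ParentFractionModel(alpha=50.0, tau1=10.0, tau2=10.0, t0=0.0)
        out = pk.apply_metabolite_correction(plasma, m)
        assert out.values[0] == pytest.approx(10.0 * np.exp(-1), rel=1e-12)

    def test_before_t0_identity(self):
        plasma = make_tac("2x2", [5.0, 7.0])  # mids 1 s, 3 s << t0
        m = pk.ParentFractionModel(alpha=55.0, tau1=6.0, tau2=120.0, t0=1.0)
        out = pk.apply_metabolite_correction(plasma, m)
        np.testing.assert_allclose(out.values, plasma.values)


class TestCorrectionRoundTrip:
    def test_generator_inversion_exact(self, schedule):
        """The generator layers the corrections inversely, so applying them
        to the generated whole-blood curve recovers the parent curve."""
        parent = pk.ParentFractionModel(alpha=55.0, tau1=6.0, tau2=120.0, t0=1.0)
        ratio = pk.PlasmaRatioModel(times=[0.0, 5.0, 90.0], ratios=[1.05, 1.15, 1.3])
        ifs = generate_input(InputModel(), schedule, parent, ratio)
        plasma = pk.apply_plasma_correction(ifs.whole_blood, ratio)
        recovered = pk.apply_metabolite_correction(plasma, parent)
        np.testing.assert_allclose(recovered.values, ifs.parent_plasma.values, rtol=1e-12)


class TestShiftInput:
    def test_zero_delay_identity(self, default_ifs):
        out = pk.shift_input(default_ifs, 0.0)
        np.testing.assert_array_equal(out.whole_blood.values, default_ifs.whole_blood.values)

    def test_peak_moves_later(self):
        # impulse-like peak at the 25-s mid shifts to the 35-s mid under a 10-s delay
        wb = make_tac("6x10", [0.0, 0.0, 100.0, 0.0, 0.0, 0.0])
        ifs = pk.build_input_set(
            wb, pk.ParentFractionModel(alpha=100.0, tau1=1e9, tau2=1e9),
            pk.PlasmaRatioModel.constant(1.0),
        )
        out = pk.shift_input(ifs, 10.0)
        assert int(np.argmax(out.whole_blood.values)) == 3  # mid 35 s holds peak mass
        assert out.whole_blood.values[3] == pytest.approx(100.0)

    def test_composition(self, default_ifs):
        a, b = 4.0, 6.0
        once = pk.shift_input(default_ifs, a + b)
        twice = pk.shift_input(pk.shift_input(default_ifs, a), b)
        # piecewise-linear resampling error only, small away from the bolus
        late = slice(45, None)
        np.testing.assert_allclose(
            twice.parent_plasma.values[late], once.parent_plasma.values[late], rtol=5e-3
        )

    def test_bounds(self, default_ifs):
        with pytest.raises(ValueError):
            pk.shift_input(default_ifs, 25.0)
        with pytest.raises(ValueError):
            pk.shift_input(default_ifs, -1.0)


class TestPerturbPeak:
    def test_unit_factor_identity(self, default_ifs):
        out = pk.perturb_peak(default_ifs, 1.0)
        np.testing.assert_allclose(out.whole_blood.values, default_ifs.whole_blood.values)

    def test_single_frame_peak(self):
        vals = np.full(10, 0.5)
        vals[4] = 100.0
        wb = make_tac("10x10", vals)
        ifs = pk.build_input_set(
            wb, pk.ParentFractionModel(alpha=100.0, tau1=1e9, tau2=1e9),
            pk.PlasmaRatioModel.constant(1.0),
        )
        out = pk.perturb_peak(ifs, 1.1)
        assert out.whole_blood.values[4] == pytest.approx(110.0)
        np.testing.assert_allclose(np.delete(out.whole_blood.values, 4), 0.5)

    def test_auc_change_bounded_by_window_share(self, default_ifs, schedule):
        # on the frame-sum representation the AUC change equals exactly
        # |factor - 1| times the peak window's AUC share
        w = peak_window(default_ifs.whole_blood.values)
        d = schedule.durations
        auc = lambda v: float((v * d).sum())
        base = auc(default_ifs.whole_blood.values)
        window_share = (default_ifs.whole_blood.values[w] * d[w]).sum() / base
        pert = pk.perturb_peak(default_ifs, 1.1)
        change = abs(auc(pert.whole_blood.values) - base) / base
        assert change <= 0.1 * window_share + 1e-12
        assert change == pytest.approx(0.1 * window_share, rel=1e-9)

    def test_max_frame_window(self, default_ifs):
        out = pk.perturb_peak(default_ifs, 1.1, window="max-frame")
        i = int(np.argmax(default_ifs.whole_blood.values))
        changed = out.whole_blood.values != default_ifs.whole_blood.values
        assert changed[i] and changed.sum() == 1

    def test_all_zero_curve(self):
        wb = make_tac("3x10", [0.0, 0.0, 0.0])
        ifs = pk.build_input_set(
            wb, pk.ParentFractionModel(alpha=100.0, tau1=1e9, tau2=1e9),
            pk.PlasmaRatioModel.constant(1.0),
        )
        with pytest.raises(ValueError):
            pk.perturb_peak(ifs, 1.05)
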