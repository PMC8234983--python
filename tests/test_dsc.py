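"""DSC processing: order tags, van't Hoff peak shape, detection, deconvolution."""

import numpy as np
import pytest
from scipy.integrate import quad

import pahunfold as pu
from pahunfold.constants import R_KCAL, celsius_to_kelvin
from pahunfold.dsc import DSCThermogram, DSCTransition
from pahunfold.errors import InvalidInputError, ProcessingOrderError


def make_raw(T, cp):
    return DSCThermogram(T, cp)


class TestBaselineAndNormalization:
    T = np.linspace(293.15, 363.15, 200)

    def test_identical_buffer_gives_zero(self):
        s = make_raw(self.T, 3.0 + 0.01 * self.T)
        out = pu.subtract_baseline(s, make_raw(self.T, 3.0 + 0.01 * self.T))
        np.testing.assert_allclose(out.cp, 0.0, atol=1e-12)
        assert out.baseline_subtracted

    def test_constant_buffer_shifts(self):
        s = make_raw(self.T, np.sin(self.T / 30))
        out = pu.subtract_baseline(s, make_raw(self.T, np.full_like(self.T, 2.5)))
        np.testing.assert_allclose(out.cp, s.cp - 2.5, atol=1e-12)

    def test_synthetic_peak_plus_drift_recovered(self):
        tr = DSCTransition(Tm=323.15, dHvH=120.0)
        peak = pu.vanthoff_excess_cp(self.T, tr)
        drift = 0.5 + 0.02 * (self.T - self.T[0])
        # buffer on a coarser, offset grid forces interpolation
        Tb = np.linspace(290.0, 366.0, 77)
        buffer = make_raw(Tb, 0.5 + 0.02 * (Tb - self.T[0]))
        out = pu.subtract_baseline(make_raw(self.T, peak + drift), buffer)
        np.testing.assert_allclose(out.cp, peak, atol=1e-6)

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(InvalidInputError):
            pu.subtract_baseline(make_raw(self.T, self.T * 0),
                                 make_raw(self.T + 100, self.T * 0))

    def test_normalization_arithmetic_and_order_tags(self):
        sub = pu.subtract_baseline(make_raw(self.T, np.ones_like(self.T)),
                                   make_raw(self.T, np.zeros_like(self.T)))
        n1 = pu.normalize(sub, conc=5.0, cell_volume=0.5)
        assert n1.cp[0] == pytest.approx(1.0 / 2.5e-9)
        n2 = pu.normalize(sub, conc=10.0, cell_volume=0.5)
        np.testing.assert_allclose(n2.cp, n1.cp / 2.0)
        with pytest.raises(ProcessingOrderError):
            pu.normalize(n1, conc=5.0, cell_volume=0.5)     # double normalization
        with pytest.raises(ProcessingOrderError):
            pu.normalize(make_raw(self.T, np.ones_like(self.T)), 5.0, 0.5)

    def test_molar_amplitude_round_trip(self):
        tr = DSCTransition(Tm=320.0, dHvH=100.0)
        molar = pu.vanthoff_excess_cp(self.T, tr)
        moles = 5e-6 * 0.5e-3
        buffer_level = 1e-8  # comparable to the raw protein signal
        raw = make_raw(self.T, molar * moles + buffer_level)
        out = pu.normalize(
            pu.subtract_baseline(raw, make_raw(self.T, np.full_like(self.T, buffer_level))),
            conc=5.0, cell_volume=0.5)
        np.testing.assert_allclose(out.cp, molar, rtol=1e-6)


class TestVantHoffPeak:
    def test_tails_vanish(self):
        tr = DSCTransition(Tm=323.15, dHvH=120.0)
        assert pu.vanthoff_excess_cp(273.15, tr) < 1e-6
        assert pu.vanthoff_excess_cp(373.15, tr) < 1e-6

    def test_value_at_tm_is_quarter_dh_squared_over_rt2(self):
        tr = DSCTransition(Tm=323.15, dHvH=120.0)
        expected = 120.0 ** 2 * 0.25 / (R_KCAL * 323.15 ** 2)
        assert pu.vanthoff_excess_cp(323.15, tr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("dH", [100.0, 150.0])
    def test_integral_equals_vanthoff_enthalpy(self, dH):
        tr = DSCTransition(Tm=323.15, dHvH=dH)
        area, _ = quad(lambda t: pu.vanthoff_excess_cp(t, tr), 293.15, 353.15)
        assert area == pytest.approx(dH, rel=0.01)

    @pytest.mark.parametrize("dH", [80.0, 120.0, 200.0])
    def test_peak_maximum_sits_just_below_tm(self, dH):
        tr = DSCTransition(Tm=323.15, dHvH=dH)
        T = np.linspace(313.15, 333.15, 200001)
        offset = 323.15 - T[np.argmax(pu.vanthoff_excess_cp(T, tr))]
        assert 0.0 < offset < 0.2


class TestTmDetection:
    def test_single_peak_within_tolerance_of_tm(self):
        tg = pu.simulate_dsc([DSCTransition(Tm=323.15, dHvH=120.0)],
                             noise=pu.NoiseModel(sigma=0.0))
        tms = pu.find_tm_first_derivative(tg)
        assert len(tms) == 1
        assert abs(tms[0] - 50.0) < 0.15

    def test_two_separated_peaks_ascending(self):
        tg = pu.simulate_dsc([DSCTransition(Tm=338.15, dHvH=150.0),
                              DSCTransition(Tm=318.15, dHvH=100.0)],
                             noise=pu.NoiseModel(sigma=0.0))
        tms = pu.find_tm_first_derivative(tg)
        assert len(tms) == 2
        assert tms == sorted(tms)
        assert abs(tms[0] - 45.0) < 0.2 and abs(tms[1] - 65.0) < 0.2

    def test_flat_thermogram_yields_empty_list(self):
        T = pu.synthetic_data.DSC_GRID_DEFAULT
        tg = DSCThermogram(T, np.full_like(T, 0.3), normalized=True,
                           baseline_subtracted=True)
        assert pu.find_tm_first_derivative(tg) == []

    def test_requires_normalized_thermogram(self):
        T = np.linspace(293.15, 363.15, 100)
        with pytest.raises(ProcessingOrderError):
            pu.find_tm_first_derivative(DSCThermogram(T, np.ones_like(T)))


class TestDeconvolution:
    def test_noiseless_two_peak_recovery_to_1e3_relative(self):
        truth = [DSCTransition(Tm=317.15, dHvH=100.0),
                 DSCTransition(Tm=328.75, dHvH=150.0)]
        tg = pu.simulate_dsc(truth, noise=pu.NoiseModel(sigma=0.0))
        trs, info = pu.deconvolve_two_transitions(tg)
        assert info["converged"] and not info["degenerate"]
        for fit, true in zip(trs, truth):
            assert abs(fit.Tm / true.Tm - 1) < 1e-3
            assert abs(fit.dHvH / true.dHvH - 1) < 1e-3

    def test_two_peak_model_beats_single_transition_fit(self):
        import lmfit
        tg = pu.simulate_preset("PAHd_DSC", seed=3)
        _, info = pu.deconvolve_two_transitions(tg)
        # independent single-peak fit on the same window
        lo, hi = info["window"]
        win = (tg.T >= lo) & (tg.T <= hi)
        Tw, cpw = tg.T[win], tg.cp[win]

        def one_peak(p):
            tr = DSCTransition(Tm=p["Tm"].value, dHvH=p["dH"].value, scale=p["s"].value)
            return p["b0"].value + pu.vanthoff_excess_cp(Tw, tr) - cpw

        params = lmfit.Parameters()
        params.add("Tm", value=Tw[np.argmax(cpw)], min=Tw[0], max=Tw[-1])
        params.add("dH", value=100.0, min=10, max=500)
        params.add("s", value=1.0, min=0, max=5)
        params.add("b0", value=float(cpw.min()))
        single = lmfit.minimize(one_peak, params, method="leastsq")
        assert info["rss"] <= float(np.sum(single.residual ** 2))

    def test_single_peak_input_flags_degenerate_second_transition(self):
        tg = pu.simulate_dsc([DSCTransition(Tm=323.15, dHvH=120.0)],
                             noise=pu.NoiseModel(sigma=0.005, seed=2))
        trs, info = pu.deconvolve_two_transitions(tg)
        assert info["degenerate"]
        main = max(trs, key=lambda t: t.scale)
        assert abs(main.Tm_celsius - 50.0) < 0.5
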