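"""Forward three-state model: frozen oracle values and structural properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pahunfold as pu
from pahunfold.constants import R_KCAL
from pahunfold.equilibrium_models import chem_free_energies, species_fractions
from pahunfold.errors import InvalidInputError

PAHT_08 = pu.ChemThermoParams(Um1=2.70, m1=1.91, Um2=5.48, m2=2.12)

finite = st.floats(min_value=-40, max_value=40, allow_nan=False)


class TestChemFreeEnergies:
    @pytest.mark.parametrize("D, expected", [
        (2.70, (0.0, None)),                 # dG1 zero at its own midpoint
        (0.0, (5.157, None)),                # m1*Um1 product
        (4.0, (None, 3.1376)),               # m2*(Um2 - 4)
    ])
    def test_linear_extrapolation_values(self, D, expected):
        dG1, dG2 = chem_free_energies(D, PAHT_08)
        if expected[0] is not None:
            assert dG1 == pytest.approx(expected[0], abs=1e-12)
        if expected[1] is not None:
            assert dG2 == pytest.approx(expected[1], abs=1e-12)

    def test_rejects_negative_or_nonfinite(self):
        with pytest.raises(InvalidInputError):
            chem_free_energies(-0.5, PAHT_08)
        with pytest.raises(InvalidInputError):
            chem_free_energies(np.nan, PAHT_08)


class TestSpeciesFractions:
    def test_half_native_half_intermediate_at_first_midpoint(self):
        fN, fI, fU = species_fractions(0.0, 50.0, 298.15)
        assert fN == pytest.approx(0.5, abs=1e-9)
        assert fI == pytest.approx(0.5, abs=1e-9)
        assert fU < 1e-12

    def test_equal_weights_when_both_free_energies_vanish(self):
        assert species_fractions(0.0, 0.0, 298.15) == pytest.approx([1 / 3] * 3)

    def test_frozen_high_precision_point(self):
        # independent arbitrary-precision evaluation of the Boltzmann weights
        fN, fI, fU = species_fractions(1.0, 2.0, 298.15)
        assert fN == pytest.approx(0.839455378238, abs=1e-9)
        assert fI == pytest.approx(0.155235996496, abs=1e-9)
        assert fU == pytest.approx(0.005308625266, abs=1e-9)

    @given(dG1=finite, dG2=finite, T=st.floats(min_value=200, max_value=400))
    def test_normalization(self, dG1, dG2, T):
        fN, fI, fU = species_fractions(dG1, dG2, T)
        assert abs(fN + fI + fU - 1.0) < 1e-12
        assert min(fN, fI, fU) >= 0.0

    @pytest.mark.parametrize("dG1, dG2", [(900.0, 900.0), (-900.0, -900.0), (900.0, -1800.0)])
    def test_extreme_free_energies_stay_finite(self, dG1, dG2):
        fracs = species_fractions(dG1, dG2, 298.15)
        assert np.all(np.isfinite(fracs))
        assert sum(fracs) == pytest.approx(1.0, abs=1e-12)

    def test_log_space_matches_naive_evaluation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dG1, dG2 = rng.uniform(-20, 20, 2)
            T = rng.uniform(250, 380)
            rt = R_KCAL * T
            w = np.array([1.0, np.exp(-dG1 / rt), np.exp(-(dG1 + dG2) / rt)])
            naive = w / w.sum()
            assert species_fractions(dG1, dG2, T) == pytest.approx(naive, rel=1e-12)


class TestChemSignal:
    def test_degenerate_baselines_collapse_to_constant(self):
        b = pu.SignalBaselines(7.0, 0, 7.0, 0, 7.0, 0)
        for D in np.linspace(0, 7.8, 15):
            assert pu.chem_signal(D, PAHT_08, b) == pytest.approx(7.0)

    def test_midpoint_average_of_native_and_intermediate(self):
        thermo = pu.ChemThermoParams(Um1=2.0, m1=2.0, Um2=30.0, m2=2.0)
        b = pu.SignalBaselines(1.0, 0, 2.0, 0, 50.0, 0)
        assert pu.chem_signal(2.0, thermo, b) == pytest.approx(1.5, abs=1e-4)

    def test_frozen_regression_value(self):
        # brute-force arbitrary-precision evaluation of the full expression
        b = pu.SignalBaselines(1.0, 0, 2.0, 0, 1.5, 0)
        assert pu.chem_signal(4.0, PAHT_08, b) == pytest.approx(1.9827079342873, abs=1e-10)

    def test_rejects_thermal_baselines(self):
        b = pu.SignalBaselines(1, 0, 2, 0, 3, 0, x_kind="thermal")
        with pytest.raises(InvalidInputError):
            pu.chem_signal(1.0, PAHT_08, b)

    @given(a=st.floats(min_value=0.1, max_value=10), b=finite)
    def test_affine_baseline_invariance(self, a, b):
        base = pu.SignalBaselines(100.0, 1.5, 190.0, -2.0, 120.0, 1.0)
        scaled = pu.SignalBaselines(a * 100 + b, a * 1.5, a * 190 + b, a * -2.0,
                                    a * 120 + b, a * 1.0)
        D = np.linspace(0, 7.8, 12)
        np.testing.assert_allclose(pu.chem_signal(D, PAHT_08, scaled),
                                   a * pu.chem_signal(D, PAHT_08, base) + b,
                                   rtol=1e-12)

    def test_two_state_reduction_when_second_transition_is_remote(self):
        # independently coded two-state sigmoid
        thermo = pu.ChemThermoParams(Um1=2.7, m1=1.91, Um2=50.0, m2=2.12)
        b = pu.SignalBaselines(100.0, 1.5, 190.0, -2.0, 120.0, 1.0)
        D = np.linspace(0, 7.8, 40)
        rt = R_KCAL * 298.15
        k = np.exp(-thermo.m1 * (thermo.Um1 - D) / rt)
        two_state = ((100.0 + 1.5 * D) + (190.0 - 2.0 * D) * k) / (1 + k)
        np.testing.assert_allclose(pu.chem_signal(D, thermo, b), two_state, atol=1e-9)


class TestThermalModel:
    def test_free_energy_vanishes_at_tm(self):
        for dH, dCp in [(80, 0), (120, 1.5), (50, 3.0)]:
            assert pu.thermal_free_energy(330.0, 330.0, dH, dCp) == pytest.approx(0.0, abs=1e-12)

    def test_enthalpy_only_value(self):
        assert pu.thermal_free_energy(310.0, 320.0, 100.0, 0.0) == pytest.approx(3.125)

    def test_null_model_is_identically_zero(self):
        T = np.linspace(280, 370, 25)
        np.testing.assert_array_equal(pu.thermal_free_energy(T, 330.0, 0.0, 0.0),
                                      np.zeros_like(T))

    def test_decreasing_through_tm(self):
        T = np.linspace(325, 335, 101)
        dG = pu.thermal_free_energy(T, 330.0, 90.0, 1.2)
        assert np.all(np.diff(dG) < 0)

    def test_midpoint_signal(self):
        thermo = pu.ThermalThermoParams(Tm1=316.15, dH1=100.0, Tm2=390.0, dH2=300.0)
        b = pu.SignalBaselines(10.0, 0, 20.0, 0, 99.0, 0, x_kind="thermal")
        assert pu.thermal_signal(316.15, thermo, b) == pytest.approx(15.0, abs=1e-3)

    def test_native_limit_far_below_tm1(self):
        thermo = pu.ThermalThermoParams(Tm1=330.0, dH1=120.0, Tm2=345.0, dH2=150.0)
        b = pu.SignalBaselines(220.0, -0.4, 230.0, -0.3, 280.0, -0.35, x_kind="thermal")
        T = 290.0
        assert pu.thermal_signal(T, thermo, b) == pytest.approx(220.0 - 0.4 * T, rel=1e-9)

    def test_frozen_regression_value(self):
        # brute-force arbitrary-precision evaluation of the full expression
        thermo = pu.ThermalThermoParams(Tm1=316.25, dH1=80.0, Tm2=327.25, dH2=120.0)
        b = pu.SignalBaselines(10.0, 0, 18.0, 0, 25.0, 0, x_kind="thermal")
        assert pu.thermal_signal(321.0, thermo, b) == pytest.approx(17.1322137577664, abs=1e-10)

    def test_invalid_temperatures_rejected(self):
        with pytest.raises(InvalidInputError):
            pu.thermal_free_energy(-5.0, 330.0, 80.0)
        with pytest.raises(InvalidInputError):
            pu.ThermalThermoParams(Tm1=-1.0, dH1=80.0, Tm2=330.0, dH2=100.0)
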