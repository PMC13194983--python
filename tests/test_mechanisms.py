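"""Rate laws: CSA, PRE dispersion, dipolar scaling, exchange, polarization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxcider import (
    DEFAULT_CONSTANTS,
    CSAParams,
    ExchangeWeights,
    GroundTruthRegistry,
    NINE_SAMPLES,
    PREParams,
    SpinConstants,
    deuteration_factor,
    exchange_weighted_rate,
    r1_csa,
    r1_pre,
    thermal_polarization,
    total_r1,
)
from relaxcider.mechanisms import deuterated_limit_t1, scale_dipolar_to_temperature

CSA_STUDY = CSAParams(delta_sigma=136.5, tau_c=7.3e-12)


class TestCSA:
    def test_value_at_9p4_tesla(self):
        # independent hand evaluation of (2/15)(B ds g)^2 tau_c
        assert r1_csa(9.4, CSA_STUDY) == pytest.approx(7.254e-3, rel=1e-3)

    def test_zero_field_zero_rate(self):
        assert r1_csa(0.0, CSA_STUDY) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=20.0))
    def test_quadratic_scaling(self, B):
        assert r1_csa(2 * B, CSA_STUDY) == pytest.approx(4 * r1_csa(B, CSA_STUDY), rel=1e-12)

    def test_loglog_slope_is_two(self):
        B = np.logspace(-5, 1, 20)
        slope = np.polyfit(np.log(B), np.log(r1_csa(B, CSA_STUDY)), 1)[0]
        assert slope == pytest.approx(2.0, abs=1e-10)

    def test_extreme_narrowing_valid_at_9p4(self):
        assert CSA_STUDY.extreme_narrowing_ok(9.4)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CSAParams(-1.0, 7.3e-12)
        with pytest.raises(ValueError):
            CSAParams(136.5, -7.3e-12)
        with pytest.raises(ValueError):
            r1_csa(-1.0, CSA_STUDY)


class TestPRE:
    O2 = PREParams(0.0066, 6.1e-12)

    def test_zero_field_equals_amplitude(self):
        assert r1_pre(0.0, self.O2) == pytest.approx(0.0066, rel=1e-12)

    def test_electron_dispersion_midpoint(self):
        # at omega_e * tau_c = 1 the electron Lorentzian halves while the
        # 13C term is still ~1: rate ~ 0.0066 * (0.3 + 0.35) ~ 4.3e-3
        B_mid = 1.0 / (DEFAULT_CONSTANTS.gamma_e * 6.1e-12)
        assert B_mid == pytest.approx(0.93, rel=0.01)
        assert r1_pre(B_mid, self.O2) == pytest.approx(4.3e-3, rel=0.01)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=1e-4, max_value=10.0))
    def test_monotone_non_increasing(self, B1, dB):
        assert r1_pre(B1, self.O2) >= r1_pre(B1 + dB, self.O2)

    def test_high_field_limit_zero(self):
        assert r1_pre(1e6, self.O2) < 1e-5 * self.O2.amplitude_zero_field

    def test_concentration_consistency_enforced(self):
        PREParams(0.0066, 6.1e-12, concentration=150.0, molar_relaxivity=0.0066 / 150.0)
        with pytest.raises(ValueError):
            PREParams(0.0066, 6.1e-12, concentration=150.0, molar_relaxivity=1.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PREParams(-0.1, 6.1e-12)
        with pytest.raises(ValueError):
            PREParams(0.0066, 0.0)


class TestDeuterationFactor:
    def test_standard_constants_give_15p9(self):
        assert DEFAULT_CONSTANTS.codata_consistent
        f = deuteration_factor()
        assert f == pytest.approx(15.9, rel=0.005)

    def test_identity_case(self):
        same = SpinConstants(gamma_D=DEFAULT_CONSTANTS.gamma_H, I_D=0.5)
        assert deuteration_factor(same) == pytest.approx(1.0, rel=1e-12)

    def test_applied_to_inter_dd_rate(self):
        # deuterated-solvent residual of the 0.0095 s^-1 protonated-water rate
        assert 0.0095 / deuteration_factor() == pytest.approx(5.97e-4, rel=0.005)


class TestExchangeWeighting:
    def test_ten_to_one_example(self):
        w = ExchangeWeights()  # 10:1 default
        assert exchange_weighted_rate(w, 0.004, 0.015) == pytest.approx(5.0e-3, rel=1e-6)

    def test_pure_py_limit(self):
        assert exchange_weighted_rate(ExchangeWeights(1.0, 0.0), 0.004, 0.015) == 0.004

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=1e-4, max_value=1.0),
        st.floats(min_value=1e-4, max_value=1.0),
    )
    def test_convex_combination(self, p, ra, rb):
        out = exchange_weighted_rate(ExchangeWeights(p, 1.0 - p), ra, rb)
        assert min(ra, rb) - 1e-15 <= out <= max(ra, rb) + 1e-15

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ExchangeWeights(0.6, 0.6)


class TestThermalPolarization:
    def test_carbon_at_1T_293K(self):
        p = thermal_polarization(DEFAULT_CONSTANTS.gamma_C, 1.0, 293.0)
        assert p == pytest.approx(8.77e-7, rel=1e-3)

    def test_zero_field(self):
        assert thermal_polarization(DEFAULT_CONSTANTS.gamma_C, 0.0, 293.0) == 0.0

    def test_high_temperature_ratio_is_gamma_ratio(self):
        pH = thermal_polarization(DEFAULT_CONSTANTS.gamma_H, 1.0, 293.0)
        pC = thermal_polarization(DEFAULT_CONSTANTS.gamma_C, 1.0, 293.0)
        assert pH / pC == pytest.approx(DEFAULT_CONSTANTS.gamma_H / DEFAULT_CONSTANTS.gamma_C,
                                        rel=1e-9)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            thermal_polarization(DEFAULT_CONSTANTS.gamma_C, 1.0, -1.0)


class TestTotalRate:
    def test_sample_H_at_1mT(self, registry):
        rate = total_r1(1e-3, NINE_SAMPLES["H"], registry)
        assert rate == pytest.approx(0.02305, rel=2e-3)
        assert 1.0 / rate == pytest.approx(43.4, rel=0.02)  # printed 43.4 +/- 1.5 s

    def test_sample_A_is_pure_background(self, registry):
        rate = total_r1(1e-3, NINE_SAMPLES["A"], registry)
        assert 1.0 / rate == pytest.approx(227.0, rel=0.005)
        assert 1.0 / rate == pytest.approx(224.5, rel=0.02)  # printed low-field mean

    @pytest.mark.parametrize("sid", sorted(NINE_SAMPLES))
    @pytest.mark.parametrize("B", [1e-5, 1e-3, 0.5, 9.4])
    def test_additivity(self, registry, sid, B):
        comp = NINE_SAMPLES[sid]
        parts = registry.mechanism_rates(B, comp)
        assert total_r1(B, comp, registry) == pytest.approx(sum(parts.values()), rel=1e-12)

    def test_component_terms_match_individual_laws(self, registry):
        # cross-check the assembled terms against direct rate-law calls
        comp, B = NINE_SAMPLES["I"], 0.25
        parts = registry.mechanism_rates(B, comp)
        assert parts["csa"] == pytest.approx(r1_csa(B, registry.csa), rel=1e-12)
        assert parts["pre_o2"] == pytest.approx(r1_pre(B, registry.pre_o2), rel=1e-12)
        assert parts["pre_metal"] == pytest.approx(r1_pre(B, registry.pre_metal_h2o), rel=1e-12)

    def test_unknown_sample_lookup_error(self):
        with pytest.raises(KeyError):
            NINE_SAMPLES["Z"]


class TestTemperatureScaling:
    def test_endpoint_factors(self):
        inter, intra = scale_dipolar_to_temperature(0.0062, 0.00068, 353.0)
        assert inter == pytest.approx(0.0062 / 2.6)
        assert intra == pytest.approx(0.00068 / 2.8)
        with pytest.raises(ValueError):
            scale_dipolar_to_temperature(1.0, 1.0, 300.0)

    def test_fully_deuterated_limit_minutes(self):
        # MD-predicted protonated dipolar rates scaled by the deuteration factor
        t1 = deuterated_limit_t1(0.0062, 0.00068, T=293.0)
        assert t1 / 60.0 == pytest.approx(39.0, rel=0.03)
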