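"""Modified Tate's-law prediction, calibration and AAD/MAD validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsize.core import DropletMeasurement, NozzleSpec, ValidationError
from capsize.synthetic import gen_prediction_study
from capsize.tate import (
    CorrectionFactors,
    calibrate,
    correction_factor_lf,
    correction_factor_sf,
    droplet_diameter,
    per_condition_factors,
    predict_diameter,
    validate,
)


class TestCorrectionFactorLF:
    def test_study_nozzle(self):
        # 19G hypodermic needle, OD 1.06 mm
        assert correction_factor_lf(1.06) == pytest.approx(0.9376, abs=1e-12)

    def test_intercept_limit(self):
        assert correction_factor_lf(1e-9) == pytest.approx(0.98)

    def test_two_mm_nozzle(self):
        assert correction_factor_lf(2.0) == pytest.approx(0.90)

    def test_accepts_nozzle_spec(self):
        assert correction_factor_lf(NozzleSpec(1.06)) == pytest.approx(0.9376)

    @pytest.mark.parametrize("d_t", [0.0, -1.0, 24.5, 30.0])
    def test_domain_errors(self, d_t):
        with pytest.raises(ValidationError):
            correction_factor_lf(d_t)


class TestDropletDiameter:
    def test_four_mm_droplet(self):
        # inverting the sphere volume: m = ρ·π·d³/6 with d = 4.000 mm
        assert droplet_diameter(3.569e-5, 1065.0) == pytest.approx(4.000, abs=5e-4)

    def test_unit_sphere(self):
        # m = π·ρ/6 kg is a 1 m sphere = 1000 mm
        rho = 1065.0
        assert droplet_diameter(math.pi * rho / 6.0, rho) == pytest.approx(1000.0)

    def test_cube_root_mass_scaling(self):
        d1 = droplet_diameter(2e-5, 1065.0)
        d2 = droplet_diameter(4e-5, 1065.0)
        assert d2 / d1 == pytest.approx(2 ** (1 / 3))

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            droplet_diameter(0.0, 1065.0)


class TestCorrectionFactorSF:
    def test_identity(self):
        assert correction_factor_sf(4.3, 4.3) == 1.0

    def test_shrinkage_ratio(self):
        assert correction_factor_sf(4.0, 4.3) == pytest.approx(4.0 / 4.3)

    def test_per_condition_is_elementwise(self):
        pairs = [(4.0, 4.0), (4.2, 4.0), (3.8, 4.0)]
        factors = per_condition_factors(pairs, NozzleSpec(1.06))
        assert [f.k_sf for f in factors] == pytest.approx([1.0, 1.05, 0.95])


class TestCalibrate:
    def test_single_pair(self):
        factors = calibrate([(0.95 * 4.0, 4.0)], NozzleSpec(1.06))
        assert factors.k_sf == pytest.approx(0.95)
        assert factors.k == pytest.approx(0.9376 * 0.95)

    def test_identical_ratios_pool_to_that_ratio(self):
        pairs = [(1.1 * d, d) for d in (3.0, 3.5, 4.0)]
        assert calibrate(pairs, NozzleSpec(1.06)).k_sf == pytest.approx(1.1)

    def test_accepts_droplet_measurements(self):
        drop = DropletMeasurement(mass=3.569e-5, density=1065.0)
        factors = calibrate([(1.3 * drop.diameter, drop)], NozzleSpec(1.06))
        assert factors.k_sf == pytest.approx(1.3)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValidationError):
            calibrate([], NozzleSpec(1.06))

    def test_monte_carlo_recovery_within_half_percent(self):
        # 100 pairs, 2% multiplicative observation noise on a known k_sf
        rng = np.random.default_rng(5)
        k_true = 1.25
        pairs = [
            (k_true * d * (1 + rng.normal(0, 0.02)), d)
            for d in rng.uniform(3.0, 4.5, size=100)
        ]
        k_hat = calibrate(pairs, NozzleSpec(1.06)).k_sf
        assert abs(k_hat / k_true - 1) < 0.005


class TestPredictDiameter:
    def test_reference_conditions_unit_k(self):
        # (6·d_t·γ/(ρ·g))^(1/3) at d_t=1.06 mm, γ=63.41 mN/m, ρ=1065 kg/m³
        assert predict_diameter(NozzleSpec(1.06), 63.41, 1065.0, 1.0) == pytest.approx(
            3.3796, abs=5e-4
        )

    def test_matches_hand_converted_si_arithmetic(self):
        # bench-unit call must equal the explicit SI evaluation exactly
        d_t_m, gamma_nm, rho, g = 1.06e-3, 63.41e-3, 1065.0, 9.81
        by_hand = (6 * d_t_m * gamma_nm / (rho * g)) ** (1 / 3) * 1000.0
        assert predict_diameter(NozzleSpec(1.06), 63.41, 1065.0, 1.0) == by_hand

    def test_cube_root_gamma_scaling(self):
        d1 = predict_diameter(NozzleSpec(1.06), 8.0, 1065.0, 1.0)
        d2 = predict_diameter(NozzleSpec(1.06), 64.0, 1065.0, 1.0)
        assert d2 / d1 == pytest.approx(2.0)

    def test_linear_in_k(self):
        base = predict_diameter(NozzleSpec(1.06), 63.41, 1065.0, 1.0)
        assert predict_diameter(
            NozzleSpec(1.06), 63.41, 1065.0, 0.9376
        ) == pytest.approx(0.9376 * base)

    def test_accepts_correction_factors(self):
        f = CorrectionFactors(k_lf=0.9376, k_sf=1.3)
        assert predict_diameter(NozzleSpec(1.06), 63.41, 1065.0, f) == pytest.approx(
            f.k * predict_diameter(NozzleSpec(1.06), 63.41, 1065.0, 1.0)
        )

    @settings(deadline=None, derandomize=True)
    @given(
        gamma=st.floats(min_value=20.0, max_value=80.0),
        rho=st.floats(min_value=950.0, max_value=1250.0),
        d_t=st.floats(min_value=0.3, max_value=3.0),
        bump=st.floats(min_value=1.01, max_value=2.0),
    )
    def test_monotonicity(self, gamma, rho, d_t, bump):
        base = predict_diameter(NozzleSpec(d_t), gamma, rho, 1.0)
        assert predict_diameter(NozzleSpec(d_t), gamma * bump, rho, 1.0) > base
        assert predict_diameter(NozzleSpec(d_t * bump), gamma, rho, 1.0) > base
        assert predict_diameter(NozzleSpec(d_t), gamma, rho * bump, 1.0) < base


class TestValidate:
    def test_identical_pairs(self):
        report = validate([(4.0, 4.0), (3.5, 3.5)])
        assert report.aad == 0.0 and report.mad == 0.0 and report.n == 2

    def test_hand_computed_two_pairs(self):
        # |4−4.4|/4 = 10%, |3−3|/3 = 0% → AAD 5, MAD 10
        report = validate([(4.0, 4.4), (3.0, 3.0)])
        assert report.aad == pytest.approx(5.0)
        assert report.mad == pytest.approx(10.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.5, max_value=10.0),
                st.floats(min_value=0.0, max_value=10.0),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_aad_never_exceeds_mad(self, pairs):
        report = validate(pairs)
        assert 0 <= report.aad <= report.mad

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            validate([])


def _run_prediction_experiment(n, seed, sigma_mass, sigma_d):
    study = gen_prediction_study(n=n, seed=seed, sigma_mass=sigma_mass,
                                 sigma_d=sigma_d)
    factors = calibrate(study.pairs, study.nozzle)
    preds = [
        (predict_diameter(study.nozzle, float(g), study.density, factors), d_obs)
        for (d_obs, _), g in zip(study.pairs, study.surface_tensions)
    ]
    return factors, validate(preds)


class TestEndToEnd:
    def test_noiseless_round_trip_is_exact(self):
        factors, report = _run_prediction_experiment(50, seed=2, sigma_mass=0.0,
                                                     sigma_d=0.0)
        assert factors.k_sf == pytest.approx(1.3, rel=1e-12)
        assert report.aad == pytest.approx(0.0, abs=1e-10)
        assert report.mad == pytest.approx(0.0, abs=1e-10)

    def test_aad_matches_half_normal_mean(self):
        # pure 2% multiplicative observation noise: E[AAD] = σ·√(2/π)·100,
        # SD of one |deviation| is σ·√(1−2/π)·100
        sigma, n = 0.02, 500
        _, report = _run_prediction_experiment(n, seed=3, sigma_mass=0.0,
                                               sigma_d=sigma)
        expected = sigma * math.sqrt(2 / math.pi) * 100
        se = sigma * math.sqrt(1 - 2 / math.pi) * 100 / math.sqrt(n)
        assert abs(report.aad - expected) < 3 * se
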