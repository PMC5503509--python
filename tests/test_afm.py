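"""Calibration, contact detection and Hertz-fit behaviour of the AFM chain."""

from dataclasses import replace

import numpy as np
import pytest

from follimech import (
    ForceCurve,
    GeneratorConfig,
    TipGeometry,
    analyze_curve,
    calibrate_spring_constant,
    detect_contact,
    fit_modulus,
    linearized_modulus,
    make_force_curve,
    make_thermal_trace,
    measure_position,
    speed_sweep,
    to_force_indentation,
)
from follimech.synthetic import make_position_curves


class TestCalibration:
    def test_recovers_nominal_10_pn_per_nm_within_2_percent(self, config):
        trace = make_thermal_trace(config, 2**17)
        k = calibrate_spring_constant(trace, config.temperature)
        assert k * 1e3 == pytest.approx(10.0, rel=0.02)

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_spring_constant(np.full(500, 1e-9), 295.0)

    def test_linear_in_temperature(self, config):
        trace = make_thermal_trace(config, 4096)
        assert calibrate_spring_constant(trace, 590.0) == pytest.approx(
            2.0 * calibrate_spring_constant(trace, 295.0))

    def test_relative_standard_error_scales_as_sqrt_2_over_n(self):
        # var_p of n Gaussians is chi-square_(n-1)-distributed: the
        # estimator's relative sd is ~sqrt(2/n); verify by Monte Carlo.
        n = 2048
        ests = []
        for seed in range(200):
            cfg = GeneratorConfig(seed=seed)
            trace = make_thermal_trace(cfg, n)
            ests.append(calibrate_spring_constant(trace, cfg.temperature))
        rel_sd = np.std(ests) / np.mean(ests)
        assert rel_sd == pytest.approx(np.sqrt(2.0 / n), rel=0.25)


class TestContactDetection:
    def test_noiseless_contact_within_one_sample_spacing(self, config, geometry):
        curve = make_force_curve(config, 70e3, contact_offset=120e-9)
        z0, d0, flags = detect_contact(curve, config.spring_constant_true, geometry)
        spacing = curve.extension[1] - curve.extension[0]
        assert not flags
        assert abs(z0 - 120e-9) <= spacing
        assert d0 == pytest.approx(0.0, abs=1e-12)

    def test_pure_baseline_flags_no_contact(self):
        z = np.linspace(0, 200e-9, 512)
        curve = ForceCurve(extension=z, deflection=np.zeros_like(z))
        _, _, flags = detect_contact(curve)
        assert "no_contact" in flags

    def test_translation_equivariance(self, config):
        curve = make_force_curve(config, 70e3)
        shift = 37e-9
        shifted = ForceCurve(extension=curve.extension + shift,
                             deflection=curve.deflection)
        z0_a, _, _ = detect_contact(curve)
        z0_b, _, _ = detect_contact(shifted)
        assert z0_b - z0_a == pytest.approx(shift, abs=1e-15)


class TestForceIndentationConversion:
    def test_force_is_spring_constant_times_deflection(self):
        z = np.linspace(0, 100e-9, 201)
        d = np.where(z > 50e-9, (z - 50e-9) * 0.1, 0.0)
        curve = ForceCurve(extension=z, deflection=d)
        delta, force = to_force_indentation(curve, 0.01, 50e-9, 0.0)
        kept = d[(z - 50e-9) - d > 0]
        np.testing.assert_allclose(force, 0.01 * kept)
        # F = k*(d-d0): a 2.357 nm deflection at 10 pN/nm is 23.57 pN
        assert 0.01 * 2.357e-9 * 1e12 == pytest.approx(23.57, rel=1e-3)

    def test_rigid_substrate_has_zero_indentation(self):
        z = np.linspace(0, 100e-9, 101)
        d = np.clip(z - 40e-9, 0.0, None)  # deflection tracks extension
        curve = ForceCurve(extension=z, deflection=d)
        delta, force = to_force_indentation(curve, 0.01, 40e-9, 0.0)
        assert delta.size == 0

    def test_contact_origin_is_zero(self, config):
        curve = make_force_curve(config, 70e3)
        delta, force = to_force_indentation(curve, 0.01, 100e-9, 0.0)
        assert np.all(delta > 0)
        assert force[np.argmin(delta)] == pytest.approx(0.0, abs=1e-14)


class TestModulusFit:
    @pytest.mark.parametrize("modulus_kpa", [1.0, 20.0, 70.0, 500.0])
    def test_noiseless_recovery_below_1e4_relative(self, config, geometry, modulus_kpa):
        curve = make_force_curve(config, modulus_kpa * 1e3)
        fit = analyze_curve(curve, config.spring_constant_true, geometry)
        assert fit.modulus == pytest.approx(modulus_kpa * 1e3, rel=1e-4)
        assert not fit.flags

    def test_linearity_in_force(self, geometry):
        delta = np.linspace(1e-9, 50e-9, 60)
        force = geometry.stiffness_prefactor(40e3) * delta**2
        e1 = fit_modulus(delta, force, geometry, refine_contact=False).modulus
        e2 = fit_modulus(delta, 2 * force, geometry, refine_contact=False).modulus
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_nonlinear_and_linearized_estimators_agree(self, config, geometry):
        # with the exact contact point both estimators see the pure
        # quadratic law and must agree to < 0.1%
        curve = make_force_curve(config, 70e3)
        z0 = curve.metadata["contact_point_true_m"]
        delta, force = to_force_indentation(curve, config.spring_constant_true, z0, 0.0)
        e_nls = fit_modulus(delta, force, geometry).modulus
        e_lin = linearized_modulus(delta, force, geometry)
        assert abs(e_nls - e_lin) / e_lin < 1e-3

    def test_quadratic_force_law_log_slope(self, config):
        curve = make_force_curve(config, 70e3)
        delta, force = to_force_indentation(
            curve, config.spring_constant_true, 100e-9, 0.0)
        sel = (delta > 1e-9) & (delta <= 50e-9)
        slope = np.polyfit(np.log(delta[sel]), np.log(force[sel]), 1)[0]
        assert slope == pytest.approx(2.00, abs=0.01)

    def test_too_few_window_samples_flagged(self, geometry):
        delta = np.linspace(1e-9, 50e-9, 5)
        force = geometry.stiffness_prefactor(40e3) * delta**2
        fit = fit_modulus(delta, force, geometry)
        assert "window_short" in fit.flags

    @pytest.mark.parametrize("modulus_kpa", [5.0, 20.0, 70.0, 200.0])
    def test_noisy_recovery_bias_and_dispersion(self, modulus_kpa):
        cfg = GeneratorConfig(seed=77, noise_fraction_deflection=0.05)
        geometry = cfg.tip_geometry()
        estimates = [
            analyze_curve(make_force_curve(cfg, modulus_kpa * 1e3, salt=i),
                          cfg.spring_constant_true, geometry).modulus
            for i in range(100)
        ]
        mean = np.mean(estimates)
        assert abs(mean - modulus_kpa * 1e3) / (modulus_kpa * 1e3) < 0.02
        assert np.std(estimates) / mean < 0.10


class TestPositionAveraging:
    def test_identical_noiseless_curves_average_exactly(self, config, geometry):
        curves = [make_force_curve(config, 30e3) for _ in range(4)]
        pm = measure_position(curves, config.spring_constant_true, geometry)
        assert pm.modulus == pytest.approx(30e3, rel=1e-6)
        assert pm.sd == pytest.approx(0.0, abs=1e-6)
        assert not pm.flagged

    def test_mean_of_distinct_fits(self, config, geometry):
        curves = [make_force_curve(config, e * 1e3) for e in (60, 70, 70, 80)]
        pm = measure_position(curves, config.spring_constant_true, geometry)
        assert pm.modulus == pytest.approx(70e3, rel=1e-4)

    def test_no_contact_curve_flags_the_position(self, config, geometry):
        curves = [make_force_curve(config, 30e3) for _ in range(3)]
        z = np.linspace(0, 200e-9, config.sample_count)
        curves.append(ForceCurve(extension=z, deflection=np.zeros_like(z)))
        pm = measure_position(curves, config.spring_constant_true, geometry)
        assert pm.flagged

    def test_wrong_count_rejected(self, config, geometry):
        with pytest.raises(ValueError):
            measure_position([make_force_curve(config, 30e3)],
                             config.spring_constant_true, geometry)


class TestSpeedSweep:
    def test_elastic_curves_are_speed_independent(self, geometry):
        sets = {}
        for speed in (0.2e-6, 0.4e-6, 0.8e-6):
            cfg = GeneratorConfig(seed=5, approach_speed=speed)
            sets[speed] = make_position_curves(cfg, 70e3, n_repeats=3)
        table = speed_sweep(sets, 0.01, geometry)
        assert table["mean_E_kPa"].max() - table["mean_E_kPa"].min() < 0.1

    def test_viscoelastic_modulus_falls_at_high_speed(self, geometry):
        sets = {}
        for speed in (0.4e-6, 0.8e-6):
            cfg = GeneratorConfig(seed=5, approach_speed=speed,
                                  viscoelastic_exponent=0.3)
            sets[speed] = make_position_curves(cfg, 70e3, n_repeats=3)
        table = speed_sweep(sets, 0.01, geometry)
        e_sorted = table.sort_values("approach_speed_um_s")["mean_E_kPa"].to_numpy()
        assert e_sorted[-1] < e_sorted[0]

    def test_single_speed_rejected(self, geometry):
        with pytest.raises(ValueError):
            speed_sweep({0.4e-6: []}, 0.01, geometry)
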