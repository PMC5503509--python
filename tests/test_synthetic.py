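"""Forward-model correctness and preset fidelity of the synthetic generator."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from follimech import (
    GeneratorConfig,
    TipGeometry,
    get_preset,
    make_follicle_phantom,
    make_force_curve,
    make_recoil_track,
    make_swelling_series,
    make_thermal_trace,
)
from follimech.afm import BOLTZMANN
from follimech.synthetic import (
    COLLAGENASE_FACTOR,
    GENOTYPES,
    required_travel,
    solve_deflection,
)

KB_295_OVER_K = 1.380649e-23 * 295.0 / 0.01  # equipartition variance oracle


def brentq_deflection(travel: np.ndarray, prefactor: float, k: float) -> np.ndarray:
    """Independent per-sample root finder for k*w = A*(s - w)^2."""
    out = np.zeros_like(travel)
    for i, s in enumerate(travel):
        if s <= 0:
            continue
        out[i] = brentq(lambda w: prefactor * (s - w) ** 2 - k * w, 0.0, s,
                        xtol=1e-15)
    return out


class TestForceCurveForwardModel:
    @pytest.mark.parametrize("modulus_kpa", [1.0, 10.0, 70.0, 500.0])
    def test_closed_form_matches_root_finding_oracle(self, config, modulus_kpa):
        geometry = config.tip_geometry()
        prefactor = geometry.stiffness_prefactor(modulus_kpa * 1e3)
        travel = np.linspace(0.0, 200e-9, 41)
        expected = brentq_deflection(travel, prefactor, config.spring_constant_true)
        got = solve_deflection(travel, prefactor, config.spring_constant_true)
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_force_at_50nm_indentation_matches_contact_formula(self):
        # E=10 kPa, nu=0.5, theta=45 deg, C=1/sqrt(2): F(50 nm) = 23.57 pN,
        # i.e. deflection 2.357 nm at k = 10 pN/nm
        geometry = TipGeometry(half_angle_deg=45.0, poisson_ratio=0.5)
        prefactor = geometry.stiffness_prefactor(10e3)
        delta = 50e-9
        force = prefactor * delta**2
        assert force * 1e12 == pytest.approx(23.570226, rel=1e-6)
        k = 0.01
        s = required_travel(delta, prefactor, k)
        w = solve_deflection(np.array([s]), prefactor, k)[0]
        assert k * w * 1e12 == pytest.approx(23.570226, rel=1e-7)
        assert w * 1e9 == pytest.approx(2.3570226, rel=1e-7)

    def test_vanishing_modulus_gives_baseline_deflection(self, config):
        curve = make_force_curve(config, modulus_true=1e-6)
        assert np.max(np.abs(curve.deflection)) < 1e-12

    def test_pre_contact_is_baseline_and_contains_50nm(self, config):
        curve = make_force_curve(config, 70e3, contact_offset=100e-9)
        pre = curve.extension < 100e-9
        assert np.all(curve.deflection[pre] == 0.0)
        assert curve.extension[pre].max() - curve.extension[0] >= 50e-9

    def test_determinism_bit_for_bit(self):
        cfg = GeneratorConfig(seed=9, noise_fraction_deflection=0.05)
        c1 = make_force_curve(cfg, 40e3)
        c2 = make_force_curve(cfg, 40e3)
        assert np.array_equal(c1.deflection, c2.deflection)
        assert np.array_equal(c1.extension, c2.extension)

    def test_rejects_bad_inputs(self, config):
        with pytest.raises(ValueError):
            make_force_curve(config, -5.0)
        with pytest.raises(ValueError):
            make_force_curve(config, 70e3, contact_offset=10e-9)
        with pytest.raises(ValueError):
            GeneratorConfig(sample_count=10)
        with pytest.raises(ValueError):
            GeneratorConfig(spring_constant_true=0.0)

    def test_viscoelastic_preset_softens_at_high_speed(self):
        slow = GeneratorConfig(seed=1, viscoelastic_exponent=0.3, approach_speed=0.4e-6)
        fast = replace(slow, approach_speed=0.8e-6)
        c_slow = make_force_curve(slow, 70e3)
        c_fast = make_force_curve(fast, 70e3)
        assert c_fast.metadata["apparent_modulus_pa"] < c_slow.metadata["apparent_modulus_pa"]


class TestThermalTrace:
    def test_variance_follows_equipartition_law(self, config):
        trace = make_thermal_trace(config, 2**17)
        assert KB_295_OVER_K == pytest.approx(4.073e-19, rel=1e-3)
        assert np.var(trace) == pytest.approx(KB_295_OVER_K, rel=0.02)
        assert np.sqrt(KB_295_OVER_K) * 1e9 == pytest.approx(0.638, abs=0.001)

    def test_rigid_cantilever_limit(self):
        stiff = GeneratorConfig(seed=1, spring_constant_true=1e6)
        trace = make_thermal_trace(stiff, 1000)
        assert np.var(trace) < 1e-25

    def test_seeded_reproducibility(self, config):
        t1 = make_thermal_trace(config, 4096)
        t2 = make_thermal_trace(config, 4096)
        assert np.array_equal(t1, t2)


class TestStiffnessPresets:
    def test_wild_type_stage_values_match_measured_biology(self):
        assert get_preset(3).modulus("central") == 30e3
        assert get_preset(5).modulus("central") == 40e3
        assert get_preset(7).modulus("central") == 70e3
        # poles ~50% softer at early stages
        for stage in (3, 5):
            p = get_preset(stage)
            assert p.modulus("pole") == pytest.approx(0.5 * p.modulus("central"))
        # central ~30% stiffer than terminal at stage 7
        p7 = get_preset(7)
        assert p7.modulus("central") / p7.modulus("terminal") == pytest.approx(1.3)
        # ~300% pole-to-center rise at stage 8
        p8 = get_preset(8)
        rise = 100 * (p8.modulus("central") - p8.modulus("pole")) / p8.modulus("pole")
        assert rise == pytest.approx(300.0)

    def test_wild_type_ordering_invariant(self):
        for stage in (3, 5, 7, 8):
            p = get_preset(stage)
            assert p.modulus("central") >= p.modulus("terminal") >= p.modulus("pole") > 0

    def test_collagenase_removes_97_percent(self):
        wt = get_preset(7)
        dig = get_preset(7, "collagenase")
        assert COLLAGENASE_FACTOR == 0.03
        for region in ("pole", "terminal", "central"):
            assert dig.modulus(region) == pytest.approx(0.03 * wt.modulus(region))

    def test_fat2_quadruples_circumferential_cv(self):
        assert get_preset(7, "fat2").circumferential_cv == pytest.approx(
            4.0 * get_preset(7, "WT").circumferential_cv)

    def test_every_genotype_has_a_preset(self):
        for g in GENOTYPES:
            p = get_preset(7, g)
            assert all(v > 0 for v in p.region_moduli.values())
        with pytest.raises(ValueError, match="unknown genotype"):
            get_preset(7, "nonexistent")


class TestPhantoms:
    def test_wild_type_profile_is_central_elevated(self, config):
        ph = make_follicle_phantom(7, "WT", config, voxel_size=(1.0, 1.0, 1.0),
                                   semi_axes=(25.0, 15.0, 15.0))
        assert ph.ground_truth["intensity_params"]["ap_amplitude"] > 0
        assert ph.image_stack.ndim == 3

    def test_fat2_circumferential_variance_at_least_4x_wt(self, config):
        wt = make_follicle_phantom(7, "WT", config)  # params only matter
        fat2 = make_follicle_phantom(7, "fat2", config, voxel_size=(2.0, 2.0, 2.0),
                                     semi_axes=(20.0, 12.0, 12.0))
        ratio = (fat2.ground_truth["intensity_params"]["circ_sd"]
                 / wt.ground_truth["intensity_params"]["circ_sd"]) ** 2
        assert ratio >= 4.0

    def test_unknown_genotype_rejected(self, config):
        with pytest.raises(ValueError, match="unknown genotype"):
            make_follicle_phantom(7, "not-a-fly", config)


class TestRecoilAndSwellingForwardModels:
    def test_small_time_displacement_is_linear(self, config):
        track = make_recoil_track(v0=2.0, L0=5.0, tau=1e6, config=config)
        # tau >> t: L(0.3) - L0 ~ v0 * t = 0.6 um
        assert track.vertex_distance[1] - 5.0 == pytest.approx(0.6, rel=1e-6)

    def test_rejects_nonpositive_parameters(self, config):
        for bad in [dict(v0=-1.0), dict(L0=0.0), dict(tau=-2.0)]:
            kwargs = dict(v0=2.0, L0=5.0, tau=5.0) | bad
            with pytest.raises(ValueError):
                make_recoil_track(config=config, **kwargs)

    def test_collagenase_bursts_at_first_post_immersion_frame(self, config):
        for salt in range(5):
            s = make_swelling_series("collagenase", config, salt=salt)
            assert s.metadata["burst_frame_true"] == 1

    def test_ehbp1_overexpression_never_bursts(self, config):
        for salt in range(5):
            s = make_swelling_series("EHBP1-OE", config, salt=salt)
            assert s.metadata["burst_frame_true"] is None

    def test_area_grows_monotonically_before_burst(self, config):
        from follimech.swelling import outline_area

        s = make_swelling_series("EHBP1-OE", config, n_frames=10)
        areas = [outline_area(o) for o in s.outlines]
        assert np.all(np.diff(areas) > 0)
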