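"""Scaled-experiment design: frequency inversion, similarity, fluid model."""

import math

import numpy as np
import pytest

from aqueductflow import (CanalGeometry, Configuration, FluidProperties,
                          OscillationSpec, PumpLimitWarning, ScalingMap,
                          SimilarityWarning, design_frequency, design_report,
                          glycerol_water_properties, map_pressure,
                          pressure_ratio, similarity_check, womersley_number)
from aqueductflow.units import bpm_to_omega


def make_config(a, L, rho, nu, omega, Ls_over_L=1.0):
    geom = CanalGeometry(length_L=L, mean_radius_a=a)
    Vs = Ls_over_L * L * geom.mean_area
    return Configuration(geom, FluidProperties(rho, nu),
                         OscillationSpec(omega=omega, stroke_volume_Vs=Vs))


class TestDesignFrequency:
    @pytest.mark.parametrize("alpha, nu, expected_bpm", [
        (2.0, 1.05e-4, 24),
        (3.0, 6.82e-5, 35),
        (4.0, 3.83e-5, 35),
    ])
    def test_bench_design_points(self, alpha, nu, expected_bpm, real_geometry):
        fluid = FluidProperties(1200.0, nu)
        design = design_frequency(alpha, real_geometry, fluid)
        assert design.bpm_rounded == expected_bpm
        assert design.within_pump_limits

    def test_unit_case(self):
        geom = CanalGeometry(length_L=2.0, mean_radius_a=1.0)
        design = design_frequency(1.0, geom, FluidProperties(1.0, 1.0))
        assert design.omega == pytest.approx(1.0, rel=1e-14)
        assert design.bpm == pytest.approx(9.549, abs=1e-3)

    def test_inverts_womersley_number(self, real_geometry):
        fluid = FluidProperties(1216.4, 6.82e-5)
        design = design_frequency(3.0, real_geometry, fluid)
        alpha = womersley_number(real_geometry, fluid, design.omega)
        assert alpha == pytest.approx(3.0, rel=1e-12)

    def test_out_of_envelope_frequency_warns(self, real_geometry):
        with pytest.warns(PumpLimitWarning):
            design = design_frequency(20.0, real_geometry,
                                      FluidProperties(1200.0, 1.05e-4))
        assert not design.within_pump_limits


class TestSimilarityCheck:
    def test_identical_configurations_have_zero_residuals(self):
        config = make_config(0.013, 0.158, 1225.6, 1.05e-4, 2.5)
        report = similarity_check(ScalingMap(human=config, experiment=config))
        assert report.passed
        assert all(r == 0.0 for r in report.residuals().values())

    def test_bench_design_is_similar_to_human_within_2pc(self):
        # human: alpha = 2 in water; bench: 10x geometry, 84/16 mixture, 24 BPM
        omega_h = 4.0 * 0.71e-6 / 0.0013**2
        human = make_config(0.0013, 0.0158, 1000.0, 0.71e-6, omega_h)
        experiment = make_config(0.013, 0.158, 1225.6, 1.05e-4, bpm_to_omega(24))
        report = similarity_check(ScalingMap(human=human, experiment=experiment))
        assert report.passed
        assert max(report.residuals().values()) < 0.02

    def test_halved_viscosity_breaks_womersley_condition(self):
        human = make_config(0.013, 0.158, 1225.6, 1.05e-4, 2.5)
        experiment = make_config(0.013, 0.158, 1225.6, 1.05e-4 / 2, 2.5)
        report = similarity_check(ScalingMap(human=human, experiment=experiment))
        assert report.womersley_residual == pytest.approx(math.sqrt(2) - 1, rel=1e-9)
        assert report.aspect_ratio_residual == 0.0
        assert report.stroke_ratio_residual == 0.0
        assert not report.passed


class TestPressureMapping:
    def make_map(self):
        omega_h = 4.0 * 0.71e-6 / 0.0013**2
        human = make_config(0.0013, 0.0158, 1000.0, 0.71e-6, omega_h)
        experiment = make_config(0.013, 0.158, 1225.6, 1.05e-4, bpm_to_omega(24))
        return ScalingMap(human=human, experiment=experiment)

    def test_bench_pressure_ratio(self):
        # (rho_E/rho_H)(nu_E/nu_H)^2 chi^-2 by direct arithmetic
        mapping = self.make_map()
        expected = 1.2256 * (1.05e-4 / 0.71e-6) ** 2 / 100.0
        assert pressure_ratio(mapping) == pytest.approx(expected, rel=1e-12)
        assert pressure_ratio(mapping) == pytest.approx(268.0, rel=0.01)

    def test_identity_map_has_unit_ratio(self):
        config = make_config(0.013, 0.158, 1225.6, 1.05e-4, 2.5)
        assert pressure_ratio(ScalingMap(config, config)) == 1.0

    def test_human_5pa_lands_in_transducer_window(self):
        # 5 Pa at human scale maps into the 100-1500 Pa design window
        mapping = self.make_map()
        dp_E = 5.0 * pressure_ratio(mapping)
        assert dp_E == pytest.approx(1340.0, rel=0.01)
        assert 100.0 <= dp_E <= 1500.0
        assert map_pressure(dp_E, mapping) == pytest.approx(5.0, rel=1e-12)

    def test_ratio_invariant_under_joint_rescaling(self):
        mapping = self.make_map()
        s = 3.7
        scaled = ScalingMap(
            human=make_config(s * 0.0013, s * 0.0158, 1000.0, 0.71e-6,
                              4.0 * 0.71e-6 / (s * 0.0013) ** 2),
            experiment=make_config(s * 0.013, s * 0.158, 1225.6, 1.05e-4,
                                   4.0 * 1.05e-4 / (s * 0.013) ** 2))
        assert pressure_ratio(scaled) == pytest.approx(pressure_ratio(mapping),
                                                       rel=1e-12)

    def test_dissimilar_map_warns(self):
        human = make_config(0.013, 0.158, 1225.6, 1.05e-4, 2.5)
        experiment = make_config(0.013, 0.158, 1225.6, 1.05e-4 / 2, 2.5)
        with pytest.warns(SimilarityWarning):
            pressure_ratio(ScalingMap(human=human, experiment=experiment))


class TestGlycerolWater:
    @pytest.mark.parametrize("fraction, nu, rho", [
        (0.84, 10.5e-5, 1225.6),
        (0.80, 6.82e-5, 1216.4),
        (0.74, 3.83e-5, 1202.2),
    ])
    def test_rig_mixtures_reproduced_exactly(self, fraction, nu, rho):
        props = glycerol_water_properties(fraction, 21.5)
        assert props.kin_viscosity_nu == nu
        assert props.density_rho == rho

    @pytest.mark.parametrize("fraction, nu_ref, rho_ref", [
        (0.84, 10.5e-5, 1225.6),
        (0.80, 6.82e-5, 1216.4),
        (0.74, 3.83e-5, 1202.2),
    ])
    def test_correlation_matches_measured_mixtures(self, fraction, nu_ref, rho_ref):
        props = glycerol_water_properties(fraction, 21.5, exact_lookup=False)
        assert props.kin_viscosity_nu == pytest.approx(nu_ref, rel=0.10)
        assert props.density_rho == pytest.approx(rho_ref, rel=0.01)

    def test_pure_water_at_body_temperature(self):
        props = glycerol_water_properties(0.0, 37.0)
        assert props.kin_viscosity_nu == pytest.approx(0.7e-6, rel=0.05)

    def test_monotone_in_glycerol_fraction(self):
        fracs = np.linspace(0.0, 1.0, 21)
        props = [glycerol_water_properties(f, 21.5, exact_lookup=False)
                 for f in fracs]
        nus = [p.kin_viscosity_nu for p in props]
        rhos = [p.density_rho for p in props]
        assert all(b > a for a, b in zip(nus, nus[1:]))
        assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            glycerol_water_properties(0.5, 150.0)
        with pytest.raises(ValueError, match="volume_fraction"):
            glycerol_water_properties(1.2, 21.5)


def test_design_report_covers_key_quantities(real_geometry):
    omega_h = 4.0 * 0.71e-6 / 0.0013**2
    human = make_config(0.0013, 0.0158, 1000.0, 0.71e-6, omega_h)
    experiment = make_config(0.013, 0.158, 1225.6, 1.05e-4, bpm_to_omega(24))
    report = design_report(ScalingMap(human=human, experiment=experiment),
                           mean_abs_Pi=0.8)
    assert report["similarity_passed"]
    assert report["chi"] == pytest.approx(10.0)
    assert report["stroke_within_pump_limits"]
    assert report["expected_dp_min_Pa"] < report["expected_dp_max_Pa"]
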