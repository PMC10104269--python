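"""Dimensionless framework: Womersley number, stroke metrics, averaging."""

import math

import numpy as np
import pytest

from aqueductflow import (CanalGeometry, DimensionlessGroups,
                          DimensionlessWaveforms, FluidProperties,
                          OscillationSpec, ParameterRangeWarning, SignalTrace,
                          mean_abs_cycle, nondimensionalize, redimensionalize,
                          stroke_metrics, trim_to_cycles, womersley_number)
from aqueductflow.units import bpm_to_omega

#: Independently computed 1e6-point trapezoid of |sin t + sin(3t)/3| / (2 pi).
MEAN_ABS_TWO_HARMONIC = 0.7073553026264573


def harmonic_flow_trace(Vs, omega, n_cycles=3, samples_per_cycle=1000):
    rate = samples_per_cycle * omega / (2 * math.pi)
    n = n_cycles * samples_per_cycle + 1
    t = np.arange(n) / rate
    return SignalTrace(0.0, rate, 0.5 * Vs * omega * np.sin(omega * t), "m3/s")


class TestWomersleyNumber:
    @pytest.mark.parametrize("a, nu, bpm, expected", [
        (0.013, 1.05e-4, 24.0, 2.01),   # bench mixture 84/16 at 24 BPM
        (0.013, 3.83e-5, 35.0, 4.02),   # bench mixture 74/26 at 35 BPM
    ])
    def test_bench_operating_points(self, a, nu, bpm, expected):
        geom = CanalGeometry(length_L=0.158, mean_radius_a=a)
        fluid = FluidProperties(1000.0, nu)
        alpha = womersley_number(geom, fluid, bpm_to_omega(bpm))
        assert alpha == pytest.approx(expected, abs=0.01)

    def test_identity_case(self):
        geom = CanalGeometry(length_L=2.0, mean_radius_a=1.0)
        assert womersley_number(geom, FluidProperties(1.0, 1.0), 1.0) == 1.0

    def test_sqrt_scaling_in_omega(self):
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        fluid = FluidProperties(1000.0, 1e-4)
        a1 = womersley_number(geom, fluid, 2.0)
        a2 = womersley_number(geom, fluid, 4.0)
        assert a2 == pytest.approx(a1 * math.sqrt(2.0), rel=1e-14)

    def test_nonpositive_inputs_rejected(self):
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        with pytest.raises(ValueError, match="omega"):
            womersley_number(geom, FluidProperties(1000.0, 1e-4), -1.0)
        with pytest.raises(ValueError, match="kin_viscosity_nu"):
            FluidProperties(1000.0, 0.0)


class TestStrokeMetrics:
    def test_harmonic_waveform_recovers_stroke_volume(self):
        Vs, omega = 80e-6, 2.5
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        got = stroke_metrics(harmonic_flow_trace(Vs, omega), geom, omega)
        assert got.Vs == pytest.approx(Vs, rel=1e-3)

    def test_square_wave_analytic_stroke(self):
        # Q = +-Q0 half a period each: Vs = (1/2) Q0 T = pi Q0 / omega
        Q0, omega = 1e-5, 3.0
        samples = 2000
        rate = samples * omega / (2 * math.pi)
        t = np.arange(2 * samples + 1) / rate
        q = Q0 * np.where((omega * t) % (2 * math.pi) < math.pi, 1.0, -1.0)
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        got = stroke_metrics(SignalTrace(0.0, rate, q, "m3/s"), geom, omega)
        assert got.Vs == pytest.approx(math.pi * Q0 / omega, rel=1e-3)

    def test_unit_stroke_length_ratio(self):
        # Vs = pi a^2 L makes Ls/L exactly 1
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        Vs = math.pi * 0.013**2 * 0.158
        omega = 2.5
        got = stroke_metrics(harmonic_flow_trace(Vs, omega), geom, omega)
        assert got.Ls_over_L == pytest.approx(1.0, rel=1e-3)

    def test_non_integer_cycles_rejected(self):
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        trace = harmonic_flow_trace(1e-5, 2.0, n_cycles=3)
        bad = trace.with_values(trace.values[:int(trace.n * 0.85)])
        with pytest.raises(ValueError, match="not an integer number"):
            stroke_metrics(bad, geom, 2.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            SignalTrace(0.0, 100.0, np.array([1.0]))


class TestMeanAbsCycle:
    @pytest.mark.parametrize("build, expected", [
        (lambda t: 3.0 * np.sin(t), 6.0 / math.pi),
        (lambda t: np.full_like(t, -2.5), 2.5),
        (lambda t: np.sin(t) + np.sin(3 * t) / 3.0, MEAN_ABS_TWO_HARMONIC),
    ])
    def test_against_analytic_and_quadrature_oracles(self, build, expected):
        omega, samples = 1.0, 20000
        rate = samples * omega / (2 * math.pi)
        t = np.arange(2 * samples + 1) / rate
        trace = SignalTrace(0.0, rate, build(omega * t))
        assert mean_abs_cycle(trace, omega) == pytest.approx(expected, rel=1e-5)

    def test_positive_homogeneity(self):
        omega, samples = 2.0, 500
        rate = samples * omega / (2 * math.pi)
        t = np.arange(samples + 1) / rate
        x = np.sin(omega * t) + 0.2 * np.cos(2 * omega * t)
        base = mean_abs_cycle(SignalTrace(0.0, rate, x), omega)
        scaled = mean_abs_cycle(SignalTrace(0.0, rate, -4.5 * x), omega)
        assert scaled == pytest.approx(4.5 * base, rel=1e-12)


class TestNondimensionalize:
    def setup_method(self):
        self.geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        self.fluid = FluidProperties(1225.6, 1.05e-4)
        self.omega = 2.5
        self.Ls = 0.158  # Ls/L = 1
        self.Vs = self.Ls * self.geom.mean_area
        self.flow = harmonic_flow_trace(self.Vs, self.omega, samples_per_cycle=400)

    def test_harmonic_flow_maps_to_half_sine(self):
        pressure = self.flow.with_values(np.zeros(self.flow.n), "Pa")
        waves = nondimensionalize(pressure, self.flow, self.fluid, self.geom,
                                  self.omega, self.Ls)
        assert np.max(np.abs(waves.Qbar)) == pytest.approx(0.5, rel=1e-4)
        expected = 0.5 * np.sin(waves.tau)
        assert np.allclose(waves.Qbar, expected, atol=1e-10)

    def test_reference_pressure_maps_to_unity(self):
        scale = self.fluid.density_rho * self.omega**2 * self.geom.length_L * self.Ls
        pressure = self.flow.with_values(np.full(self.flow.n, scale), "Pa")
        waves = nondimensionalize(pressure, self.flow, self.fluid, self.geom,
                                  self.omega, self.Ls)
        assert np.allclose(waves.Pi, 1.0, rtol=1e-14)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        p_vals = rng.normal(size=self.flow.n)
        pressure = self.flow.with_values(p_vals, "Pa")
        waves = nondimensionalize(pressure, self.flow, self.fluid, self.geom,
                                  self.omega, self.Ls)
        dp, q = redimensionalize(waves, self.fluid, self.geom, self.omega, self.Ls)
        assert np.allclose(dp, p_vals, rtol=1e-12)
        assert np.allclose(q, self.flow.values, rtol=1e-12)

    def test_mismatched_traces_rejected(self):
        pressure = SignalTrace(0.0, self.flow.rate, np.zeros(self.flow.n - 5), "Pa")
        with pytest.raises(ValueError, match="length"):
            nondimensionalize(pressure, self.flow, self.fluid, self.geom,
                              self.omega, self.Ls)


class TestDomainTypes:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            CanalGeometry(length_L=0.01, mean_radius_a=0.02)  # a/L >= 1
        with pytest.raises(ValueError):
            CanalGeometry(length_L=0.1, mean_radius_a=0.01,
                          area_profile=((0.0, 1e-4), (0.05, -1e-4), (0.1, 1e-4)))

    def test_tabulated_waveform_must_be_zero_mean(self):
        q = np.sin(np.linspace(0, 2 * math.pi, 256, endpoint=False)) + 0.3
        with pytest.raises(ValueError, match="net volume"):
            OscillationSpec(omega=1.0, stroke_volume_Vs=1e-6,
                            waveform="tabulated", tabulated_Q=q)

    def test_groups_warn_outside_typical_ranges(self):
        geom = CanalGeometry(length_L=0.158, mean_radius_a=0.013)
        fluid = FluidProperties(1000.0, 1.05e-4)
        osc = OscillationSpec(omega=50.0, stroke_volume_Vs=1e-4)  # alpha >> 4
        with pytest.warns(ParameterRangeWarning):
            DimensionlessGroups.from_configuration(geom, fluid, osc)

    def test_waveforms_require_uniform_phase(self):
        tau = np.array([0.0, 0.1, 0.5])
        with pytest.raises(ValueError, match="uniform"):
            DimensionlessWaveforms(tau=tau, Pi=np.zeros(3), Qbar=np.zeros(3))


def test_trim_to_cycles_keeps_whole_periods():
    omega = 2.0
    rate = 200 * omega / (2 * math.pi)
    t = np.arange(520) / rate  # 2.6 cycles
    trace = SignalTrace(0.0, rate, np.sin(omega * t))
    trimmed, k = trim_to_cycles(trace, omega)
    assert k == 2
    assert trimmed.duration == pytest.approx(2 * 2 * math.pi / omega, rel=5e-3)
    with pytest.raises(ValueError, match="insufficient cycles"):
        trim_to_cycles(trace, omega, min_cycles=5)
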