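"""Synthetic pump/transducer recordings with realistic measurement defects.

The generator inverts the measurement chain: a prescribed periodic flow rate
is fed through the forward flow model to obtain the pressure channel, and
integrated (divided by the piston area) to obtain the pump piston-position
channel.  The defects of the real acquisition are then emulated:

* the piston voltage is digitized by a 10-bit ADC over a full-scale range
  of 1.2x the commanded stroke, so the position carries a quantization
  staircase;
* the serial readout occasionally produces single-sample spikes two orders
  of magnitude above the signal peak (Poisson-placed, default ~0.5 per 1000
  samples);
* both channels carry additive Gaussian noise;
* sampling rates differ: 80 Hz for pressure, 2500 Hz for position.

Two waveforms are available.  ``harmonic`` is the textbook stroke
``Q = (1/2) Vs omega sin(omega t)``.  ``physiologic`` is a frozen
8-harmonic synthesis standing in for a cardiac-gated PC-MRI aqueduct
waveform: systolic-dominant, with three local maxima and three minima per
cycle echoing the percussion, tidal and dicrotic waves of intracranial
pressure.  It is a synthetic stand-in — its harmonic content is documented
here, not measured from a subject — and is always rescaled so that
``(1/2) \\oint |Q| dt`` equals the commanded stroke volume exactly.

All randomness derives from a single integer seed; a given seed reproduces
a recording bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (CanalGeometry, DimensionlessGroups, FluidProperties,
                   SignalTrace, _require_positive)
from .model import HarmonicDecomposition, ModelConfig, evaluate_on_phase
from .pipeline import RawRecording

__all__ = [
    "NoiseSpec",
    "PHYSIOLOGIC_HARMONICS",
    "physiologic_decomposition",
    "make_waveform",
    "simulate_recording",
    "PISTON_AREA",
    "PRESSURE_RATE",
    "PISTON_RATE",
]

#: Pressure-channel and piston-channel sampling rates [Hz].
PRESSURE_RATE = 80.0
PISTON_RATE = 2500.0

#: Pump piston area [m^2] (50 mm bore class pulsatile pump, ~25 cm^2).
PISTON_AREA = 25e-4

#: ADC full-scale range as a multiple of the commanded peak-to-peak stroke.
ADC_FULL_SCALE_FACTOR = 1.2

#: Frozen harmonic content of the physiologic stand-in waveform, prior to
#: stroke normalization: Q(tau) proportional to sum_n Re[c_n e^{i n tau}].
#: Systolic-dominant (peak/|trough| ~ 1.3) with exactly three local maxima
#: and three minima per cycle.
PHYSIOLOGIC_HARMONICS: dict[int, complex] = {
    1: 0.5 * np.exp(-0.5j * np.pi),
    2: 0.09 * np.exp(1.5j * np.pi),
    3: 0.10 * np.exp(1.125j * np.pi),
    4: 0.02 * np.exp(0.5j),
    5: 0.012 * np.exp(1.5j),
    6: 0.007 * np.exp(2.0j),
    7: 0.004 * np.exp(0.3j),
    8: 0.002 * np.exp(1.0j),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-defect model for the synthetic acquisition chain.

    Noise standard deviations are fractions of the relevant signal scale
    (pressure peak; peak-to-peak stroke); ``spike_rate`` is the expected
    number of readout spikes per 1000 piston samples and
    ``spike_magnitude`` their size as a multiple of the signal peak.
    """

    pressure_noise_sd: float = 0.02
    position_noise_sd: float = 0.001
    spike_rate: float = 0.5
    spike_magnitude: float = 100.0
    adc_bits: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pressure_noise_sd", "position_noise_sd",
                     "spike_rate", "spike_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseSpec":
        """Noiseless acquisition (24-bit ADC, no spikes, no Gaussian noise)."""
        return cls(pressure_noise_sd=0.0, position_noise_sd=0.0,
                   spike_rate=0.0, spike_magnitude=0.0, adc_bits=24, seed=seed)

    @classmethod
    def pressure_only(cls, sd: float, seed: int = 0) -> "NoiseSpec":
        """Gaussian pressure noise only, otherwise ideal acquisition."""
        return replace(cls.none(seed=seed), pressure_noise_sd=sd)


def _normalized_physiologic() -> dict[int, complex]:
    """Physiologic coefficients scaled so (1/2) \\oint |Qbar| dtau = 1.

    This matches the harmonic convention (Qbar = (1/2) sin tau integrates
    to exactly 1), so Qbar = Q / (omega Vs) for both waveforms.
    """
    tau = np.linspace(0.0, 2.0 * math.pi, 8192, endpoint=False)
    q = np.zeros_like(tau)
    for n, c in PHYSIOLOGIC_HARMONICS.items():
        q += np.real(c * np.exp(1j * n * tau))
    scale = 0.5 * np.mean(np.abs(q)) * 2.0 * math.pi
    return {n: c / scale for n, c in PHYSIOLOGIC_HARMONICS.items()}


def physiologic_decomposition(fundamental: float = 1.0) -> HarmonicDecomposition:
    """Stroke-normalized physiologic stand-in as a harmonic decomposition."""
    return HarmonicDecomposition(fundamental, _normalized_physiologic())


def waveform_decomposition(kind: str, fundamental: float = 1.0) -> HarmonicDecomposition:
    """Dimensionless decomposition of a named waveform kind."""
    if kind == "harmonic":
        return HarmonicDecomposition.harmonic(fundamental)
    if kind == "physiologic":
        return physiologic_decomposition(fundamental)
    raise ValueError(f"unknown waveform kind {kind!r}")


def make_waveform(kind: str, Vs: float, omega: float,
                  n_samples_per_cycle: int = 1000) -> SignalTrace:
    """One period of the flow rate Q(t) [m^3/s] for a named waveform.

    ``harmonic`` gives ``Q = (1/2) Vs omega sin(omega t)``; ``physiologic``
    synthesizes the frozen 8-harmonic stand-in.  Both are scaled so the
    trapezoidal stroke volume ``(1/2) \\oint |Q| dt`` equals ``Vs`` exactly
    in the continuum limit.
    """
    _require_positive(Vs=Vs, omega=omega)
    if n_samples_per_cycle < 16:
        raise ValueError("n_samples_per_cycle must be >= 16")
    dec = waveform_decomposition(kind)
    tau = np.linspace(0.0, 2.0 * math.pi, n_samples_per_cycle, endpoint=False)
    qbar = np.zeros_like(tau)
    for n, c in dec.coefficients.items():
        qbar += np.real(c * np.exp(1j * n * tau))
    rate = n_samples_per_cycle * omega / (2.0 * math.pi)
    return SignalTrace(t0=0.0, rate=rate, values=omega * Vs * qbar, units="m3/s")


def simulate_recording(waveform: str,
                       geometry: CanalGeometry,
                       fluid: FluidProperties,
                       omega: float,
                       Ls_over_L: float,
                       model: ModelConfig = ModelConfig(),
                       noise: NoiseSpec = NoiseSpec(),
                       n_cycles: int = 40,
                       piston_area: float = PISTON_AREA,
                       ) -> RawRecording:
    """Generate a raw two-channel recording consistent with the flow model.

    The pressure channel is the model's Pi(tau), redimensionalized and
    sampled at 80 Hz; the piston channel is the cumulative trapezoidal
    integral of Q(t)/piston_area at 2500 Hz, centred so it starts and ends
    at the same value, then noised, digitized and spiked per ``noise``.
    """
    _require_positive(omega=omega, Ls_over_L=Ls_over_L, piston_area=piston_area)
    if n_cycles < 5:
        raise ValueError("n_cycles must be >= 5 for stable cycle averages")

    rng = np.random.default_rng(noise.seed)
    Ls = Ls_over_L * geometry.length_L
    Vs = Ls * geometry.mean_area
    period = 2.0 * math.pi / omega
    duration = n_cycles * period

    dec = waveform_decomposition(waveform, fundamental=omega)
    n_harm = 1 if waveform == "harmonic" else max(dec.coefficients)
    config = replace(model, n_harmonics=max(model.n_harmonics, n_harm)
                     if waveform != "harmonic" else 1)
    groups = DimensionlessGroups(
        alpha=math.sqrt(omega * geometry.mean_radius_a**2 / fluid.kin_viscosity_nu),
        Ls_over_L=Ls_over_L, a_over_L=geometry.aspect_ratio)

    # pressure channel at 80 Hz
    n_p = int(math.floor(duration * PRESSURE_RATE)) + 1
    t_p = np.arange(n_p) / PRESSURE_RATE
    _, Pi_p = evaluate_on_phase(dec, groups, config, omega * t_p, geometry)
    dp = Pi_p * fluid.density_rho * omega**2 * geometry.length_L * Ls
    if noise.pressure_noise_sd > 0:
        dp = dp + rng.normal(0.0, noise.pressure_noise_sd * np.max(np.abs(dp)),
                             size=dp.shape)

    # piston channel at 2500 Hz: integrate Q, centre, noise, digitize, spike
    n_x = int(math.floor(duration * PISTON_RATE)) + 1
    t_x = np.arange(n_x) / PISTON_RATE
    Qbar_x, _ = evaluate_on_phase(dec, groups, config, omega * t_x, geometry)
    Q_x = Qbar_x * omega * Vs  # Qbar is stroke-normalized: Q = omega Vs Qbar
    x = cumulative_trapezoid(Q_x / piston_area, t_x, initial=0.0)
    x = x - 0.5 * (np.max(x) + np.min(x))
    stroke_pp = np.max(x) - np.min(x)
    if noise.position_noise_sd > 0:
        x = x + rng.normal(0.0, noise.position_noise_sd * stroke_pp, size=x.shape)
    full_scale = ADC_FULL_SCALE_FACTOR * stroke_pp
    step = full_scale / 2**noise.adc_bits
    x = np.clip(np.round(x / step) * step, -full_scale / 2, full_scale / 2)
    if noise.spike_rate > 0:
        n_spikes = rng.poisson(noise.spike_rate * n_x / 1000.0)
        if n_spikes:
            idx = rng.integers(0, n_x, size=n_spikes)
            sign = rng.choice((-1.0, 1.0), size=n_spikes)
            x[idx] = sign * noise.spike_magnitude * np.max(np.abs(x))

    return RawRecording(
        pressure=SignalTrace(0.0, PRESSURE_RATE, dp, "Pa"),
        piston_position=SignalTrace(0.0, PISTON_RATE, x, "m"),
        piston_area=piston_area, geometry=geometry, fluid=fluid,
        omega=omega, waveform=waveform, nominal_Ls_over_L=Ls_over_L)
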