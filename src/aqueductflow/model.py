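"""Forward flow model: dimensionless pressure from a prescribed flow rate.

For fully developed oscillatory flow in a rigid circular tube, each Fourier
harmonic of the flow rate maps onto a harmonic of the axial pressure
difference through the complex impedance

    Zhat_n = i n / F(alpha_n),      alpha_n = alpha sqrt(n),
    F(alpha) = 1 - 2 J1(Lambda) / (Lambda J0(Lambda)),
    Lambda = i^{3/2} alpha,

with J0, J1 the complex Bessel functions of the first kind (Womersley's
solution, written so that ``Pihat_n = Zhat_n Qbarhat_n`` in the
nondimensional variables of :mod:`aqueductflow.core`).  Two classic limits
anchor the model: ``F -> i alpha^2 / 8`` for alpha -> 0 recovers quasi-steady
Poiseuille resistance (pressure in phase with flow) while ``F -> 1`` for
alpha -> infinity leaves the pure inertial reactance i n (pressure leading
flow by pi/2).

The nearly inviscid entrance regions where the canal meets the ventricles
add a minor loss quadratic in velocity.  The total dimensionless pressure is

    Pi(tau) = sum_n Re[Zhat_n Qbarhat_n e^{i n tau}]
              + (K/2) (Ls/L) ubar |ubar|,

with ``ubar`` the dimensionless section-mean velocity (equal to Qbar for a
uniform tube referenced to the mean radius) and K an entrance-loss
coefficient.  K defaults to 0.7 — the sum of typical rounded-entry and
sudden-expansion minor-loss coefficients — and is an explicit calibration
knob.  An optional quasi-one-dimensional variable-area treatment sums the
per-slice uniform-tube impedance along a measured area profile; it is an
approximation, not a 3-D solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import jv

from .core import (CanalGeometry, DimensionlessGroups, DimensionlessWaveforms,
                   PressureSummary, _require_positive)

__all__ = [
    "HarmonicDecomposition",
    "ModelConfig",
    "womersley_F",
    "womersley_impedance",
    "evaluate_on_phase",
    "predict_pressure",
]

#: Largest |Lambda| for which the Bessel evaluation stays inside double range.
_MAX_BESSEL_ARG = 600.0

#: Net-flux tolerance: |c_0| relative to the largest harmonic amplitude.
_NET_FLUX_TOL = 1e-8


@dataclass(frozen=True)
class HarmonicDecomposition:
    """Fourier representation of a zero-mean periodic dimensionless flow.

    ``Qbar(tau) = sum_n Re[coefficients[n] e^{i n tau}]`` for harmonic
    indices n >= 1 of the fundamental angular frequency.  There is no n=0
    term: a periodic stroke displaces zero net volume.
    """

    fundamental: float
    coefficients: Mapping[int, complex]

    def __post_init__(self) -> None:
        _require_positive(fundamental=self.fundamental)
        coeffs = {int(n): complex(c) for n, c in self.coefficients.items()}
        if not coeffs:
            raise ValueError("at least one harmonic coefficient is required")
        if any(n < 1 for n in coeffs):
            raise ValueError("harmonic indices must be >= 1 (zero-mean waveform)")
        object.__setattr__(self, "coefficients", coeffs)

    @classmethod
    def harmonic(cls, fundamental: float = 1.0,
                 amplitude: float = 0.5) -> "HarmonicDecomposition":
        """The single-harmonic stroke ``Qbar = amplitude * sin(tau)``."""
        return cls(fundamental, {1: -1j * amplitude})

    @classmethod
    def from_samples(cls, Qbar: np.ndarray, fundamental: float = 1.0,
                     n_harmonics: int = 8,
                     max_rms_error: float = 0.005) -> "HarmonicDecomposition":
        """Decompose one period of uniformly sampled Qbar.

        Raises when the waveform carries net volume flux or when truncation
        to ``n_harmonics`` leaves a relative RMS reconstruction error above
        ``max_rms_error``.
        """
        q = np.asarray(Qbar, dtype=float)
        if q.ndim != 1 or q.size < 2 * n_harmonics + 2:
            raise ValueError("need one period with at least 2*(n_harmonics+1) samples")
        spec = np.fft.rfft(q)
        scale = np.max(np.abs(spec[1:])) if spec.size > 1 else 0.0
        if scale == 0.0:
            raise ValueError("waveform has no oscillatory content")
        if abs(spec[0]) > 1e-6 * scale:
            raise ValueError("waveform carries net volume flux (nonzero mean)")
        coeffs = {n: 2.0 * spec[n] / q.size
                  for n in range(1, min(n_harmonics, spec.size - 1) + 1)}
        dec = cls(fundamental, coeffs)
        rms = np.sqrt(np.mean((dec.synthesize(q.size) - q) ** 2))
        ref = np.sqrt(np.mean(q**2))
        if rms > max_rms_error * ref:
            raise ValueError(
                f"truncation to {n_harmonics} harmonics leaves RMS error "
                f"{rms / ref:.2%} > {max_rms_error:.2%}; increase n_harmonics")
        return dec

    @property
    def n_harmonics(self) -> int:
        return max(self.coefficients)

    def synthesize(self, n_samples: int) -> np.ndarray:
        """Evaluate Qbar(tau) on a uniform phase grid of ``n_samples``."""
        tau = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
        out = np.zeros(n_samples)
        for n, c in self.coefficients.items():
            out += np.real(c * np.exp(1j * n * tau))
        return out


@dataclass(frozen=True)
class ModelConfig:
    """Flow-model configuration.

    ``n_harmonics`` caps the harmonic superposition (use >= 8 for
    anharmonic cardiac-like waveforms, mirroring the 8x fundamental
    bandwidth such waveforms need); ``entrance_loss_K`` is the quadratic
    minor-loss coefficient; ``use_area_profile`` switches the linear term to
    the per-slice variable-area treatment when the geometry carries a
    profile.
    """

    n_harmonics: int = 8
    entrance_loss_K: float = 0.7
    use_area_profile: bool = False

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.entrance_loss_K < 0:
            raise ValueError("entrance_loss_K must be >= 0")


def womersley_F(alpha: float | np.ndarray) -> complex | np.ndarray:
    """Womersley bracket ``F(alpha) = 1 - 2 J1(Lambda)/(Lambda J0(Lambda))``.

    ``Lambda = i^{3/2} alpha``.  F relates the section-mean velocity to the
    driving pressure gradient; ``F -> i alpha^2/8`` as alpha -> 0 and
    ``F -> 1`` as alpha -> infinity.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    if np.any(alpha > _MAX_BESSEL_ARG):
        raise ValueError(
            f"alpha = {float(np.max(alpha)):.3g} too large for stable Bessel "
            "evaluation; cap the number of harmonics (alpha_n = alpha*sqrt(n))")
    lam = 1j**1.5 * alpha
    out = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return complex(out) if out.ndim == 0 else out


def womersley_impedance(alpha_n: float, harmonic: int = 1,
                        geometry: CanalGeometry | None = None,
                        use_area_profile: bool = False) -> complex:
    """Complex impedance ``Zhat_n`` with ``Pihat_n = Zhat_n Qbarhat_n``.

    ``alpha_n`` is the per-harmonic Womersley number ``alpha sqrt(n)`` and
    ``harmonic`` the index n.  For a uniform rigid tube,
    ``Zhat_n = i n / F(alpha_n)``.  With ``use_area_profile`` and a geometry
    carrying an area profile, the per-slice uniform-tube impedance (local
    radius, local section velocity) is integrated along the canal.
    """
    _require_positive(alpha_n=alpha_n)
    if harmonic < 1:
        raise ValueError("harmonic index must be >= 1")
    if use_area_profile and geometry is not None and geometry.area_profile:
        return _profile_impedance(alpha_n, harmonic, geometry)
    return 1j * harmonic / womersley_F(alpha_n)


def _profile_impedance(alpha_n: float, harmonic: int,
                       geometry: CanalGeometry) -> complex:
    """Series sum of per-slice impedances along the area profile.

    Each slice of local radius r(x) behaves as a uniform tube with local
    Womersley number alpha_n r/a and local section velocity Q/A(x); the
    dimensionless pressure contributions add in series:

        Zhat_n = (1/L) \\int_0^L [i n / F(alpha_n r/a)] (pi a^2 / A(x)) dx.
    """
    xs = np.array([x for x, _ in geometry.area_profile])
    As = np.array([A for _, A in geometry.area_profile])
    a = geometry.mean_radius_a
    r_local = np.sqrt(As / math.pi)
    F_local = womersley_F(alpha_n * r_local / a)
    integrand = (1j * harmonic / F_local) * (math.pi * a**2 / As)
    return complex(np.trapezoid(integrand, xs) / geometry.length_L)


def evaluate_on_phase(waveform: HarmonicDecomposition,
                      groups: DimensionlessGroups,
                      config: ModelConfig,
                      tau: np.ndarray,
                      geometry: CanalGeometry | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (Qbar, Pi) of the model at arbitrary phases ``tau`` [rad]."""
    tau = np.asarray(tau, dtype=float)
    Qbar = np.zeros_like(tau)
    Pi = np.zeros_like(tau)
    for n, c in sorted(waveform.coefficients.items()):
        if n > config.n_harmonics:
            continue
        Z = womersley_impedance(groups.alpha * math.sqrt(n), harmonic=n,
                                geometry=geometry,
                                use_area_profile=config.use_area_profile)
        phase = np.exp(1j * n * tau)
        Qbar += np.real(c * phase)
        Pi += np.real(Z * c * phase)
    if config.entrance_loss_K > 0.0:
        ubar = Qbar  # section-mean velocity referenced to the mean radius
        Pi = Pi + 0.5 * config.entrance_loss_K * groups.Ls_over_L * ubar * np.abs(ubar)
    return Qbar, Pi


def predict_pressure(waveform: HarmonicDecomposition,
                     groups: DimensionlessGroups,
                     config: ModelConfig = ModelConfig(),
                     geometry: CanalGeometry | None = None,
                     n_samples: int = 4096,
                     ) -> tuple[DimensionlessWaveforms, PressureSummary]:
    """Predict Pi(tau) and its cycle summary for a prescribed Qbar(tau).

    Returns the phase-resolved dimensionless waveforms on a uniform
    ``n_samples``-point grid together with a :class:`PressureSummary`
    carrying the cycle-averaged magnitude <|Pi|> (trapezoidal rule) and the
    fundamental-mode phase lag phi (positive: pressure leads flow).
    """
    tau = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    Qbar, Pi = evaluate_on_phase(waveform, groups, config, tau, geometry)

    # uniform periodic phase grid -> the mean equals the trapezoidal average
    mean_abs_Pi = float(np.mean(np.abs(Pi)))
    phi = _fundamental_phase_difference(Pi, Qbar)
    waves = DimensionlessWaveforms(tau=tau, Pi=Pi, Qbar=Qbar)
    summary = PressureSummary(mean_abs_Pi=mean_abs_Pi, phase_lag_phi=phi,
                              groups=groups)
    return waves, summary


def _fundamental_phase_difference(Pi: np.ndarray, Qbar: np.ndarray) -> float:
    """Phase of the fundamental FFT bin of Pi minus that of Qbar, in (-pi, pi]."""
    fp = np.fft.rfft(Pi)
    fq = np.fft.rfft(Qbar)
    phi = float(np.angle(fp[1]) - np.angle(fq[1]))
    phi = (phi + math.pi) % (2.0 * math.pi) - math.pi
    if phi == -math.pi:  # wrap convention: phi in (-pi, pi]
        phi = math.pi
    return phi
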