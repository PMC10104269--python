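"""Dimensionless framework for oscillatory flow in a narrow canal.

The oscillatory motion of cerebrospinal fluid through the cerebral aqueduct
is governed, after dimensional reduction, by three dimensionless groups:

* the aspect ratio ``a/L`` of the canal (mean radius over length),
* the dimensionless stroke length ``Ls/L`` with ``Ls = Vs / (pi a^2)``,
* the Womersley number ``alpha = sqrt(omega a^2 / nu)``.

The cycle-averaged magnitude of the interventricular pressure difference,
``<|dp|>``, made dimensionless as ``<|Pi|> = <|dp|> / (rho omega^2 L Ls)``,
is then a function of those three groups alone.  This module houses the
group definitions, stroke metrics, trapezoidal cycle averaging and the
nondimensionalization of measured pressure/flow traces,

    Pi(tau)   = dp / (rho omega^2 L Ls),
    Qbar(tau) = Q / (omega pi a^2 Ls),          tau = omega t.

All quantities are SI internally; unit conversions live in
:mod:`aqueductflow.units`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ParameterRangeWarning",
    "SignalTrace",
    "CanalGeometry",
    "FluidProperties",
    "OscillationSpec",
    "DimensionlessGroups",
    "DimensionlessWaveforms",
    "StrokeMetrics",
    "PressureSummary",
    "womersley_number",
    "stroke_metrics",
    "mean_abs_cycle",
    "nondimensionalize",
    "redimensionalize",
    "trim_to_cycles",
]

# Typical physiological ranges; outside them the framework still applies
# but results are extrapolations, so the package warns rather than errors.
A_OVER_L_RANGE = (1.0 / 20.0, 1.0 / 10.0)
LS_OVER_L_RANGE = (0.5, 1.5)
ALPHA_RANGE = (2.0, 4.0)

#: Fractional tolerance (of one period) for treating a trace as covering an
#: integer number of cycles.
CYCLE_TOLERANCE = 0.01


class ParameterRangeWarning(UserWarning):
    """A dimensionless group lies outside its typical physiological range."""


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0.0 and math.isfinite(value)):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled time series.

    Parameters
    ----------
    t0 : float
        Time of the first sample [s].
    rate : float
        Sampling frequency [Hz].
    values : ndarray
        Samples; units recorded in ``units`` ('Pa', 'm', 'm3/s', '1').
    """

    t0: float
    rate: float
    values: np.ndarray
    units: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate!r}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Time spanned from first to last sample [s]."""
        return (self.n - 1) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SignalTrace":
        return SignalTrace(self.t0, self.rate, values, units or self.units)


@dataclass(frozen=True)
class CanalGeometry:
    """Canal (aqueduct) geometry: length, mean radius, optional area profile.

    ``area_profile`` is a sequence of ``(x, A)`` pairs giving the lumen
    cross-section area [m^2] at axial position x [m], with x strictly
    increasing from 0 to ``length_L``.
    """

    length_L: float
    mean_radius_a: float
    area_profile: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        _require_positive(length_L=self.length_L, mean_radius_a=self.mean_radius_a)
        if not 0.0 < self.mean_radius_a / self.length_L < 1.0:
            raise ValueError("aspect ratio a/L must lie in (0, 1)")
        if self.area_profile is not None:
            prof = tuple((float(x), float(A)) for x, A in self.area_profile)
            object.__setattr__(self, "area_profile", prof)
            xs = np.array([x for x, _ in prof])
            As = np.array([A for _, A in prof])
            if np.any(As <= 0):
                raise ValueError("area_profile areas must all be positive")
            if np.any(np.diff(xs) <= 0):
                raise ValueError("area_profile axial positions must be strictly increasing")
            if not (abs(xs[0]) <= 1e-12 * self.length_L and
                    abs(xs[-1] - self.length_L) <= 1e-9 * self.length_L):
                raise ValueError("area_profile must span 0 to length_L")

    @property
    def aspect_ratio(self) -> float:
        """a/L, dimensionless."""
        return self.mean_radius_a / self.length_L

    @property
    def mean_area(self) -> float:
        """pi a^2 [m^2], the reference cross-section."""
        return math.pi * self.mean_radius_a**2


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid density [kg/m^3] and kinematic viscosity [m^2/s]."""

    density_rho: float
    kin_viscosity_nu: float

    def __post_init__(self) -> None:
        _require_positive(density_rho=self.density_rho,
                          kin_viscosity_nu=self.kin_viscosity_nu)


#: CSF-like water properties (density and kinematic viscosity at body
#: temperature differ negligibly from CSF).
CSF_WATER = FluidProperties(density_rho=1000.0, kin_viscosity_nu=0.71e-6)


@dataclass(frozen=True)
class OscillationSpec:
    """Oscillation frequency, stroke volume and waveform identity.

    The stroke volume is ``Vs = (1/2) \\oint |Q| dt`` over one period; an
    optional tabulated one-period flow-rate waveform may be attached for
    ``waveform='tabulated'`` and must displace zero net volume.
    """

    omega: float
    stroke_volume_Vs: float
    waveform: str = "harmonic"
    tabulated_Q: np.ndarray | None = None

    def __post_init__(self) -> None:
        _require_positive(omega=self.omega, stroke_volume_Vs=self.stroke_volume_Vs)
        if self.waveform not in ("harmonic", "physiologic", "tabulated"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.waveform == "tabulated":
            if self.tabulated_Q is None:
                raise ValueError("tabulated waveform requires tabulated_Q samples")
            q = np.asarray(self.tabulated_Q, dtype=float)
            object.__setattr__(self, "tabulated_Q", q)
            scale = np.max(np.abs(q))
            if scale > 0 and abs(np.mean(q)) > 1e-6 * scale:
                raise ValueError("tabulated waveform must displace zero net volume per period")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega


@dataclass(frozen=True)
class DimensionlessGroups:
    """The three governing groups: alpha, Ls/L and a/L."""

    alpha: float
    Ls_over_L: float
    a_over_L: float

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha, Ls_over_L=self.Ls_over_L,
                          a_over_L=self.a_over_L)

    @classmethod
    def from_configuration(cls, geometry: CanalGeometry, fluid: FluidProperties,
                           oscillation: OscillationSpec,
                           warn: bool = True) -> "DimensionlessGroups":
        alpha = womersley_number(geometry, fluid, oscillation.omega)
        Ls = oscillation.stroke_volume_Vs / geometry.mean_area
        groups = cls(alpha=alpha, Ls_over_L=Ls / geometry.length_L,
                     a_over_L=geometry.aspect_ratio)
        if warn:
            groups.warn_if_outside_typical_ranges()
        return groups

    def warn_if_outside_typical_ranges(self) -> None:
        checks = (("a/L", self.a_over_L, A_OVER_L_RANGE),
                  ("Ls/L", self.Ls_over_L, LS_OVER_L_RANGE),
                  ("alpha", self.alpha, ALPHA_RANGE))
        for name, value, (lo, hi) in checks:
            if not lo <= value <= hi:
                warnings.warn(
                    f"{name} = {value:.4g} lies outside the typical physiological "
                    f"range [{lo:.3g}, {hi:.3g}]; results are extrapolations",
                    ParameterRangeWarning, stacklevel=3)


@dataclass(frozen=True)
class DimensionlessWaveforms:
    """Phase-resolved dimensionless pressure Pi(tau) and flow Qbar(tau).

    ``tau`` is the oscillation phase omega*t, reduced modulo 2*pi, on a
    uniform underlying time grid; for multi-cycle traces it wraps as a
    sawtooth.  Pi and Qbar are expected to be (close to) zero-mean.
    """

    tau: np.ndarray
    Pi: np.ndarray
    Qbar: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        Pi = np.asarray(self.Pi, dtype=float)
        Qbar = np.asarray(self.Qbar, dtype=float)
        for name, arr in (("tau", tau), ("Pi", Pi), ("Qbar", Qbar)):
            object.__setattr__(self, name, arr)
        if not (tau.shape == Pi.shape == Qbar.shape):
            raise ValueError("tau, Pi and Qbar must have identical shapes")
        if np.any(tau < 0) or np.any(tau >= 2 * math.pi):
            raise ValueError("tau must lie in [0, 2*pi)")
        dtau = np.diff(tau) % (2 * math.pi)
        if dtau.size and not np.allclose(dtau, dtau[0], rtol=0, atol=1e-9 + 1e-6 * dtau[0]):
            raise ValueError("tau must advance uniformly (mod 2*pi)")


class StrokeMetrics(NamedTuple):
    Vs: float
    Ls: float
    Ls_over_L: float


@dataclass(frozen=True)
class PressureSummary:
    """Cycle-averaged summary of a pressure/flow pair.

    ``mean_abs_Pi`` is the cycle-averaged magnitude of the dimensionless
    pressure, ``phase_lag_phi`` the fundamental-mode phase of the pressure
    minus that of the flow (positive when pressure peaks first), wrapped to
    (-pi, pi].  ``mean_abs_dp`` carries the dimensional counterpart
    ``mean_abs_Pi * rho omega^2 L Ls`` [Pa] when the dimensional context is
    known (None for purely dimensionless model evaluations).
    """

    mean_abs_Pi: float
    phase_lag_phi: float
    groups: DimensionlessGroups
    mean_abs_dp: float | None = None
    n_cycles_used: int | None = None

    def __post_init__(self) -> None:
        if self.mean_abs_Pi < 0:
            raise ValueError("mean_abs_Pi must be non-negative")
        if not -math.pi < self.phase_lag_phi <= math.pi + 1e-12:
            raise ValueError("phase_lag_phi must lie in (-pi, pi]")


def womersley_number(geometry: CanalGeometry, fluid: FluidProperties,
                     omega: float) -> float:
    """Womersley number ``alpha = sqrt(omega a^2 / nu)``.

    Doubling omega multiplies alpha by sqrt(2); alpha compares the
    oscillatory-inertial scale to the viscous diffusion scale across the
    canal radius.
    """
    _require_positive(omega=omega)
    return math.sqrt(omega * geometry.mean_radius_a**2 / fluid.kin_viscosity_nu)


def _check_integer_cycles(duration: float, omega: float) -> int:
    """Number of whole periods in ``duration``; raise if not integer within 1%."""
    period = 2.0 * math.pi / omega
    n_cycles = duration / period
    rounded = round(n_cycles)
    if rounded < 1:
        raise ValueError(
            f"insufficient cycles: trace covers {n_cycles:.3g} periods, need >= 1")
    if abs(n_cycles - rounded) > CYCLE_TOLERANCE:
        raise ValueError(
            f"trace covers {n_cycles:.4g} periods, not an integer number within "
            f"{CYCLE_TOLERANCE:.0%} of a period; trim with trim_to_cycles first")
    return rounded


def trim_to_cycles(trace: SignalTrace, omega: float,
                   min_cycles: int = 1) -> tuple[SignalTrace, int]:
    """Trim a trace to the largest whole number of periods from its start.

    Returns the trimmed trace and the number of cycles kept.  Raises when
    fewer than ``min_cycles`` whole periods are available.
    """
    period = 2.0 * math.pi / omega
    k = int(math.floor(trace.duration / period + CYCLE_TOLERANCE))
    if k < min_cycles:
        raise ValueError(
            f"insufficient cycles: trace covers {trace.duration / period:.3g} "
            f"periods, need >= {min_cycles}")
    n_keep = int(round(k * period * trace.rate)) + 1
    n_keep = min(n_keep, trace.n)
    return trace.with_values(trace.values[:n_keep]), k


def mean_abs_cycle(trace: SignalTrace, omega: float) -> float:
    """Cycle-averaged magnitude ``(omega/2pi) \\oint |x| dt`` by trapezoid.

    The trace must cover an integer number of periods (within 1% of one
    period); the average is taken over all cycles present.
    """
    _require_positive(omega=omega)
    _check_integer_cycles(trace.duration, omega)
    integral = np.trapezoid(np.abs(trace.values), dx=1.0 / trace.rate)
    return float(integral / trace.duration)


def stroke_metrics(flow_trace: SignalTrace, geometry: CanalGeometry,
                   omega: float) -> StrokeMetrics:
    """Stroke volume, stroke length and Ls/L from a flow-rate trace.

    ``Vs = (1/2) \\oint |Q| dt`` per cycle (trapezoidal rule, averaged over
    the cycles present) and ``Ls = Vs / (pi a^2)``.
    """
    _require_positive(omega=omega)
    n_cycles = _check_integer_cycles(flow_trace.duration, omega)
    integral = np.trapezoid(np.abs(flow_trace.values), dx=1.0 / flow_trace.rate)
    Vs = 0.5 * integral / n_cycles
    Ls = Vs / geometry.mean_area
    return StrokeMetrics(Vs=Vs, Ls=Ls, Ls_over_L=Ls / geometry.length_L)


def _check_synchronized(pressure_trace: SignalTrace, flow_trace: SignalTrace) -> None:
    if pressure_trace.n != flow_trace.n:
        raise ValueError("pressure and flow traces must have the same length")
    if not math.isclose(pressure_trace.rate, flow_trace.rate, rel_tol=1e-9):
        raise ValueError("pressure and flow traces must share one sampling rate")
    if abs(pressure_trace.t0 - flow_trace.t0) * pressure_trace.rate > 1e-6:
        raise ValueError("pressure and flow traces must be time-aligned")


def nondimensionalize(pressure_trace: SignalTrace, flow_trace: SignalTrace,
                      fluid: FluidProperties, geometry: CanalGeometry,
                      omega: float, Ls: float) -> DimensionlessWaveforms:
    """Map (dp [Pa], Q [m^3/s]) onto (Pi(tau), Qbar(tau)).

    ``Pi = dp / (rho omega^2 L Ls)`` and ``Qbar = Q / (omega pi a^2 Ls)``
    with phase ``tau = omega (t - t0) mod 2 pi``.
    """
    _require_positive(omega=omega, Ls=Ls)
    _check_synchronized(pressure_trace, flow_trace)
    _check_integer_cycles(pressure_trace.duration, omega)
    t = np.arange(pressure_trace.n) / pressure_trace.rate
    tau = (omega * t) % (2.0 * math.pi)
    # guard against rounding pushing a phase to exactly 2*pi
    tau[tau >= 2.0 * math.pi] = 0.0
    p_scale = fluid.density_rho * omega**2 * geometry.length_L * Ls
    q_scale = omega * geometry.mean_area * Ls
    return DimensionlessWaveforms(tau=tau,
                                  Pi=pressure_trace.values / p_scale,
                                  Qbar=flow_trace.values / q_scale)


def redimensionalize(waves: DimensionlessWaveforms, fluid: FluidProperties,
                     geometry: CanalGeometry, omega: float,
                     Ls: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`nondimensionalize`: returns (dp [Pa], Q [m^3/s])."""
    _require_positive(omega=omega, Ls=Ls)
    p_scale = fluid.density_rho * omega**2 * geometry.length_L * Ls
    q_scale = omega * geometry.mean_area * Ls
    return waves.Pi * p_scale, waves.Qbar * q_scale
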