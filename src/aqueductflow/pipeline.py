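"""Processing chain from raw bench recordings to (<|Pi|>, phi).

A recording pairs a differential-pressure channel (Pa, 80 Hz) with a
pulsatile-pump piston-position channel (m, 2500 Hz).  The chain is:

1. despike the piston channel (Hampel filter: rolling median + scaled MAD),
2. resample it, with anti-alias filtering, onto the 80 Hz pressure rate,
3. differentiate (central differences) and multiply by the piston area to
   obtain the flow rate Q(t),
4. zero-phase low-pass both channels at a multiple of the drive frequency
   (5x for harmonic runs, 8x for anharmonic cardiac-like runs),
5. align by timestamps (pressure interpolated onto the piston-derived grid),
6. trim to a whole number of cycles, zero-average the pressure,
7. nondimensionalize and compute the cycle-averaged pressure magnitude
   <|Pi|> (trapezoidal rule) and the fundamental-mode phase lag phi.

phi is the FFT phase of the pressure fundamental minus that of the flow
fundamental, wrapped to (-pi, pi]; a positive value means the pressure
difference peaks before the flow rate.

The module also provides a model/results pair in the statsmodels idiom:
:class:`RecordingAnalysis` wraps a recording plus processing options, and
its :meth:`~RecordingAnalysis.fit` returns :class:`PressureResults` carrying
the estimates, their cycle-to-cycle dispersion, diagnostics, ``summary()``
and ``plot()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import (CanalGeometry, DimensionlessGroups, DimensionlessWaveforms,
                   FluidProperties, PressureSummary, SignalTrace,
                   mean_abs_cycle, nondimensionalize, stroke_metrics,
                   trim_to_cycles, womersley_number, CYCLE_TOLERANCE)
from .units import bpm_to_omega

__all__ = [
    "RawRecording",
    "hampel_despike",
    "lowpass",
    "resample_trace",
    "position_to_flowrate",
    "phase_lag",
    "process_experiment",
    "RecordingAnalysis",
    "PressureResults",
]

#: Default Hampel threshold in robust standard deviations.
HAMPEL_N_SIGMAS = 5.0
#: Default Hampel half-window as a fraction of one period.
HAMPEL_WINDOW_PERIODS = 0.1
#: Gaussian-consistency factor converting MAD to a standard deviation.
MAD_SCALE = 1.4826
#: Low-pass cutoff as a multiple of the drive frequency, per waveform kind.
CUTOFF_MULTIPLES = {"harmonic": 5.0, "physiologic": 8.0, "tabulated": 8.0}
#: Fraction of a period discarded at each end before cycle trimming, to keep
#: filter edge transients out of the averaged window.
EDGE_GUARD_PERIODS = 0.5


@dataclass(frozen=True)
class RawRecording:
    """A raw bench recording with its configuration.

    ``pressure`` is the differential pressure [Pa], ``piston_position`` the
    pump piston position [m]; ``piston_area`` [m^2] converts piston velocity
    to volumetric flow rate.  Recordings shorter than 5 common cycles are
    accepted with a warning (the processing itself requires at least 2).
    """

    pressure: SignalTrace
    piston_position: SignalTrace
    piston_area: float
    geometry: CanalGeometry
    fluid: FluidProperties
    omega: float
    waveform: str = "harmonic"
    nominal_Ls_over_L: float | None = None

    def __post_init__(self) -> None:
        if self.piston_area <= 0:
            raise ValueError("piston_area must be strictly positive")
        if self.omega <= 0:
            raise ValueError("omega must be strictly positive")
        if self.waveform not in CUTOFF_MULTIPLES:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        start, stop = self.common_interval()
        if stop <= start:
            raise ValueError("pressure and piston recordings do not overlap in time")
        n_cycles = (stop - start) * self.omega / (2.0 * math.pi)
        if n_cycles < 5.0 - CYCLE_TOLERANCE:
            warnings.warn(
                f"recording covers only {n_cycles:.2g} common cycles; at least "
                "5 are recommended for stable cycle averages",
                UserWarning, stacklevel=3)

    def common_interval(self) -> tuple[float, float]:
        """Overlap [start, stop] of the two channels' timestamps [s]."""
        start = max(self.pressure.t0, self.piston_position.t0)
        stop = min(self.pressure.t0 + self.pressure.duration,
                   self.piston_position.t0 + self.piston_position.duration)
        return start, stop


def hampel_despike(trace: SignalTrace, window_halfwidth: int,
                   n_sigmas: float = HAMPEL_N_SIGMAS) -> SignalTrace:
    """Replace outliers by the rolling median (Hampel filter).

    A sample deviating from the rolling median (window ``2*halfwidth + 1``)
    by more than ``n_sigmas * 1.4826 * MAD`` — MAD being the rolling median
    absolute deviation — is replaced by that median; all other samples pass
    through unchanged.
    """
    if window_halfwidth < 1:
        raise ValueError("window_halfwidth must be >= 1 sample")
    hw = int(window_halfwidth)
    size = 2 * hw + 1
    if size > trace.n:
        raise ValueError(
            f"Hampel window ({size} samples) longer than trace ({trace.n})")
    x = trace.values
    # Classic per-window statistics: for each window, the median m and the
    # MAD about that same m.  (Comparing each sample against its *own*
    # rolling median instead would deflate the MAD near smooth extrema and
    # flag legitimate curvature.)  Chunked to bound the sliding-window
    # memory footprint.
    padded = np.pad(x, hw, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, size)
    med = np.empty_like(x)
    mad = np.empty_like(x)
    chunk = max(1, int(4e6 // size))
    for a in range(0, x.size, chunk):
        b = min(a + chunk, x.size)
        w = windows[a:b]
        m = np.median(w, axis=1)
        med[a:b] = m
        mad[a:b] = np.median(np.abs(w - m[:, None]), axis=1)
    bad = np.abs(x - med) > n_sigmas * MAD_SCALE * mad
    out = x.copy()
    out[bad] = med[bad]
    return trace.with_values(out)


def lowpass(trace: SignalTrace, cutoff_hz: float, order: int = 4) -> SignalTrace:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The forward-backward application doubles the effective order and
    cancels the phase response exactly, which is essential: any filter
    phase at the fundamental would bias the measured phase lag.
    """
    nyquist = trace.rate / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz!r} Hz must lie in (0, Nyquist={nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.rate, output="sos")
    return trace.with_values(signal.sosfiltfilt(sos, trace.values))


def resample_trace(trace: SignalTrace, new_rate: float) -> SignalTrace:
    """Resample to ``new_rate`` with polyphase anti-alias filtering."""
    if new_rate <= 0:
        raise ValueError("new_rate must be positive")
    frac = Fraction(new_rate / trace.rate).limit_denominator(10_000)
    values = signal.resample_poly(trace.values, frac.numerator, frac.denominator,
                                  padtype="line")
    return SignalTrace(trace.t0, trace.rate * frac.numerator / frac.denominator,
                       values, trace.units)


def position_to_flowrate(recording: RawRecording,
                         despike: bool = True) -> SignalTrace:
    """Flow rate Q(t) [m^3/s] at the pressure rate from the piston channel.

    Order of operations: despike at the native rate, resample (anti-alias)
    to the pressure sampling rate, differentiate by central differences
    (one-sided at the endpoints), multiply by the piston area.  Low-pass
    filtering is left to the caller so the cutoff can track the drive
    frequency.
    """
    piston = recording.piston_position
    if despike:
        halfwidth = max(1, int(round(
            HAMPEL_WINDOW_PERIODS * 2.0 * math.pi / recording.omega * piston.rate)))
        halfwidth = min(halfwidth, (piston.n - 1) // 2)
        piston = hampel_despike(piston, halfwidth)
    piston = resample_trace(piston, recording.pressure.rate)
    dxdt = np.gradient(piston.values, 1.0 / piston.rate)
    return SignalTrace(piston.t0, piston.rate, recording.piston_area * dxdt,
                       units="m3/s")


def phase_lag(Qbar: SignalTrace, Pi: SignalTrace, omega: float) -> float:
    """Fundamental-mode phase of Pi minus that of Qbar, wrapped to (-pi, pi].

    Both traces must be synchronized and cover at least two whole cycles
    (one cycle gives no frequency resolution around the fundamental).  The
    fundamental is taken as the FFT bin nearest omega/(2 pi).
    """
    if Qbar.n != Pi.n or not math.isclose(Qbar.rate, Pi.rate, rel_tol=1e-9):
        raise ValueError("Qbar and Pi traces must be synchronized")
    n_cycles = Pi.duration * omega / (2.0 * math.pi)
    if n_cycles < 2.0 - CYCLE_TOLERANCE:
        raise ValueError(
            f"insufficient cycles for phase estimation: {n_cycles:.3g} < 2")
    freqs = np.fft.rfftfreq(Pi.n, d=1.0 / Pi.rate)
    k = int(np.argmin(np.abs(freqs - omega / (2.0 * math.pi))))
    if k == 0:
        raise ValueError("fundamental falls in the DC bin; trace too short")
    phi = float(np.angle(np.fft.rfft(Pi.values)[k])
                - np.angle(np.fft.rfft(Qbar.values)[k]))
    phi = (phi + math.pi) % (2.0 * math.pi) - math.pi
    if phi == -math.pi:
        phi = math.pi
    return phi


def _aligned_channels(recording: RawRecording) -> tuple[SignalTrace, SignalTrace]:
    """Flow and pressure on one common 80 Hz grid, filtered and aligned."""
    omega = recording.omega
    f0 = omega / (2.0 * math.pi)
    cutoff = CUTOFF_MULTIPLES[recording.waveform] * f0

    flow = position_to_flowrate(recording)
    flow = lowpass(flow, cutoff)
    pressure = lowpass(recording.pressure, cutoff)

    # common window on the flow grid; pressure linearly interpolated onto it
    start, stop = recording.common_interval()
    grid_t0 = flow.t0 + math.ceil((start - flow.t0) * flow.rate - 1e-9) / flow.rate
    n_grid = int(math.floor((stop - grid_t0) * flow.rate + 1e-9)) + 1
    grid = grid_t0 + np.arange(n_grid) / flow.rate
    q = np.interp(grid, flow.times, flow.values)
    p = np.interp(grid, pressure.times, pressure.values)
    return (SignalTrace(grid_t0, flow.rate, q, "m3/s"),
            SignalTrace(grid_t0, flow.rate, p, "Pa"))


def process_experiment(recording: RawRecording,
                       return_waveforms: bool = False,
                       ) -> PressureSummary | tuple[PressureSummary, DimensionlessWaveforms]:
    """Full chain from a raw recording to its pressure summary.

    Raises ``ValueError`` (tagged with the failing stage) when any stage's
    contract is violated; the most common is ``insufficient cycles`` for
    recordings shorter than the edge guard plus two whole periods.
    """
    omega = recording.omega
    period = 2.0 * math.pi / omega
    try:
        flow, pressure = _aligned_channels(recording)
    except ValueError as err:
        raise ValueError(f"alignment stage: {err}") from err

    # guard the filter edge transients, then trim to whole cycles
    guard = int(round(EDGE_GUARD_PERIODS * period * flow.rate))
    if flow.n <= 2 * guard + 2:
        raise ValueError("trimming stage: insufficient cycles in recording")
    q_vals = flow.values[guard:flow.n - guard]
    p_vals = pressure.values[guard:flow.n - guard]
    t0 = flow.t0 + guard / flow.rate
    flow = SignalTrace(t0, flow.rate, q_vals, "m3/s")
    pressure = SignalTrace(t0, flow.rate, p_vals, "Pa")
    try:
        flow, n_cycles = trim_to_cycles(flow, omega, min_cycles=2)
    except ValueError as err:
        raise ValueError(f"trimming stage: {err}") from err
    pressure = pressure.with_values(pressure.values[:flow.n])

    # zero-average the pressure over the trimmed whole-cycle window
    pressure = pressure.with_values(pressure.values - np.mean(pressure.values))

    metrics = stroke_metrics(flow, recording.geometry, omega)
    groups = DimensionlessGroups(
        alpha=womersley_number(recording.geometry, recording.fluid, omega),
        Ls_over_L=metrics.Ls_over_L,
        a_over_L=recording.geometry.aspect_ratio)
    waves = nondimensionalize(pressure, flow, recording.fluid,
                              recording.geometry, omega, metrics.Ls)
    Pi_trace = SignalTrace(t0, flow.rate, waves.Pi, "1")
    Qbar_trace = SignalTrace(t0, flow.rate, waves.Qbar, "1")
    summary = PressureSummary(
        mean_abs_Pi=mean_abs_cycle(Pi_trace, omega),
        phase_lag_phi=phase_lag(Qbar_trace, Pi_trace, omega),
        groups=groups,
        mean_abs_dp=mean_abs_cycle(pressure, omega),
        n_cycles_used=n_cycles)
    if return_waveforms:
        return summary, waves
    return summary


# ---------------------------------------------------------------------------
# Model/results facade
# ---------------------------------------------------------------------------

class RecordingAnalysis:
    """Estimation model for one bench recording.

    Wraps a :class:`RawRecording`; :meth:`fit` runs the processing chain and
    returns a :class:`PressureResults`.  Construct directly from arrays, or
    from CSV files with :meth:`from_csv` (two files: ``t_s, dp_Pa`` and
    ``t_s, x_m``).
    """

    def __init__(self, recording: RawRecording):
        self.recording = recording

    @classmethod
    def from_csv(cls, pressure_csv: str | Path, piston_csv: str | Path,
                 geometry: CanalGeometry, fluid: FluidProperties,
                 omega: float | None = None, bpm: float | None = None,
                 piston_area: float = 25e-4, waveform: str = "harmonic",
                 nominal_Ls_over_L: float | None = None) -> "RecordingAnalysis":
        if (omega is None) == (bpm is None):
            raise ValueError("specify exactly one of omega or bpm")
        if omega is None:
            omega = bpm_to_omega(bpm)
        pressure = _read_trace_csv(pressure_csv, value_column=1, units="Pa")
        piston = _read_trace_csv(piston_csv, value_column=1, units="m")
        rec = RawRecording(pressure=pressure, piston_position=piston,
                           piston_area=piston_area, geometry=geometry,
                           fluid=fluid, omega=omega, waveform=waveform,
                           nominal_Ls_over_L=nominal_Ls_over_L)
        return cls(rec)

    def fit(self) -> "PressureResults":
        summary, waves = process_experiment(self.recording, return_waveforms=True)
        per_cycle = _per_cycle_mean_abs(waves.Pi, summary.n_cycles_used)
        return PressureResults(model=self, summary=summary, waveforms=waves,
                               per_cycle_mean_abs_Pi=per_cycle)


@dataclass(frozen=True)
class PressureResults:
    """Results of fitting a :class:`RecordingAnalysis`.

    ``per_cycle_mean_abs_Pi`` holds the cycle-by-cycle averages behind the
    pooled estimate; their standard error quantifies run stability (it does
    not include systematic contributions such as transducer calibration).
    """

    model: RecordingAnalysis
    summary: PressureSummary
    waveforms: DimensionlessWaveforms
    per_cycle_mean_abs_Pi: np.ndarray

    @property
    def mean_abs_Pi(self) -> float:
        return self.summary.mean_abs_Pi

    @property
    def phase_lag_phi(self) -> float:
        return self.summary.phase_lag_phi

    @property
    def mean_abs_dp(self) -> float | None:
        return self.summary.mean_abs_dp

    @property
    def mean_abs_Pi_stderr(self) -> float:
        k = self.per_cycle_mean_abs_Pi.size
        if k < 2:
            return float("nan")
        return float(np.std(self.per_cycle_mean_abs_Pi, ddof=1) / math.sqrt(k))

    def summary_frame(self) -> pd.DataFrame:
        s, g = self.summary, self.summary.groups
        rows = {
            "mean_abs_Pi": s.mean_abs_Pi,
            "mean_abs_Pi_stderr": self.mean_abs_Pi_stderr,
            "phase_lag_phi_rad": s.phase_lag_phi,
            "mean_abs_dp_Pa": s.mean_abs_dp,
            "alpha": g.alpha,
            "Ls_over_L": g.Ls_over_L,
            "a_over_L": g.a_over_L,
            "n_cycles_used": s.n_cycles_used,
        }
        return pd.DataFrame({"value": rows})

    def summary_text(self) -> str:
        frame = self.summary_frame()
        lines = ["Recording pressure analysis",
                 "-" * 33]
        for name, value in frame["value"].items():
            lines.append(f"{name:>20s} : {value:.6g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Phase-wrapped Pi(tau) and Qbar(tau) over the analysed cycles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(self.waveforms.tau)
        ax.plot(self.waveforms.tau[order], self.waveforms.Pi[order],
                ".", ms=2, label=r"$\Pi(\tau)$")
        ax.plot(self.waveforms.tau[order], self.waveforms.Qbar[order],
                ".", ms=2, label=r"$\bar{Q}(\tau)$")
        ax.set_xlabel(r"$\tau$ [rad]")
        ax.legend()
        return ax


def _per_cycle_mean_abs(Pi: np.ndarray, n_cycles: int) -> np.ndarray:
    """Trapezoidal mean |Pi| per cycle (sample-index cycle boundaries)."""
    n = Pi.size
    bounds = np.round(np.linspace(0, n - 1, n_cycles + 1)).astype(int)
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2:
            out.append(np.trapezoid(np.abs(Pi[a:b + 1])) / (b - a))
    return np.asarray(out)


def _read_trace_csv(path: str | Path, value_column: int, units: str) -> SignalTrace:
    frame = pd.read_csv(path)
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    x = frame.iloc[:, value_column].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, np.median(dt), rtol=1e-3, atol=0):
        raise ValueError(f"{path}: time column must be uniformly sampled")
    return SignalTrace(t0=float(t[0]), rate=1.0 / float(np.median(dt)),
                       values=x, units=units)
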