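"""Clinical endpoint: mean transmantle pressure from MRI-measurable inputs.

The cycle-averaged magnitude of the transmantle (interventricular) pressure
difference follows from the dimensionless description as

    <|dp|> = <|Pi|> rho omega^2 L Vs / (pi a^2),

with the stroke volume Vs and the cardiac angular frequency omega measured
by phase-contrast MRI and the aqueduct length L and mean radius a taken
from anatomical imaging (L is user-supplied; conventions for where the
canal "ends" differ between segmentations, and the estimate scales linearly
with it).  When <|Pi|> is not supplied it is computed by the forward flow
model at the implied (alpha, Ls/L, a/L), by default with the physiologic
stand-in waveform — the harmonic waveform changes <|Pi|> by only a few
percent.

Because <|Pi|> itself falls with the Womersley number alpha = a sqrt(omega/nu),
enlarging the aqueduct reduces the estimate faster than the explicit a^-2:
patients with simultaneously increased stroke volume and an enlarged
aqueduct may still show normal transmantle pressures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core import (CanalGeometry, DimensionlessGroups, FluidProperties,
                   CSF_WATER, _require_positive)
from .model import ModelConfig, predict_pressure

__all__ = ["TransmantleEstimate", "estimate_transmantle"]

#: Womersley range over which the harmonic-superposition model is trusted.
ALPHA_VALID_RANGE = (0.5, 10.0)


@dataclass(frozen=True)
class TransmantleEstimate:
    """Mean transmantle pressure estimate and the groups behind it."""

    mean_abs_dp: float          # [Pa]
    mean_abs_Pi: float          # dimensionless
    phase_lag_phi: float | None  # [rad]; None when mean_abs_Pi was supplied
    groups: DimensionlessGroups
    alpha_in_valid_range: bool


def estimate_transmantle(Vs: float, omega: float, geometry: CanalGeometry,
                         fluid: FluidProperties = CSF_WATER,
                         mean_abs_Pi: float | None = None,
                         waveform: str = "physiologic",
                         config: ModelConfig = ModelConfig(),
                         ) -> TransmantleEstimate:
    """Estimate ``<|dp|> = <|Pi|> rho omega^2 L Vs/(pi a^2)`` [Pa].

    Parameters
    ----------
    Vs : float
        Stroke volume [m^3] (``(1/2) \\oint |Q| dt`` from PC-MRI).
    omega : float
        Cardiac angular frequency [rad/s].
    geometry, fluid
        Aqueduct anatomy and CSF properties (water-like by default).
    mean_abs_Pi : float, optional
        Dimensionless pressure level; computed by the flow model when
        omitted.  Zero gives a zero estimate.
    waveform : str
        Waveform for the model evaluation ('physiologic' default or
        'harmonic'; the two agree within a few percent).
    """
    _require_positive(Vs=Vs, omega=omega)
    if mean_abs_Pi is not None and mean_abs_Pi < 0:
        raise ValueError("mean_abs_Pi must be non-negative")

    alpha = math.sqrt(omega * geometry.mean_radius_a**2 / fluid.kin_viscosity_nu)
    Ls = Vs / geometry.mean_area
    groups = DimensionlessGroups(alpha=alpha, Ls_over_L=Ls / geometry.length_L,
                                 a_over_L=geometry.aspect_ratio)
    in_range = ALPHA_VALID_RANGE[0] <= alpha <= ALPHA_VALID_RANGE[1]
    if not in_range:
        warnings.warn(
            f"alpha = {alpha:.3g} outside the validated range "
            f"{ALPHA_VALID_RANGE}; the model evaluation is an extrapolation",
            UserWarning, stacklevel=2)

    phi: float | None = None
    if mean_abs_Pi is None:
        from .synthetic import waveform_decomposition  # local: avoids cycle

        dec = waveform_decomposition(waveform, fundamental=omega)
        _, summary = predict_pressure(dec, groups, config, geometry=geometry)
        mean_abs_Pi = summary.mean_abs_Pi
        phi = summary.phase_lag_phi

    dp = (mean_abs_Pi * fluid.density_rho * omega**2 * geometry.length_L
          * Vs / geometry.mean_area)
    return TransmantleEstimate(mean_abs_dp=dp, mean_abs_Pi=mean_abs_Pi,
                               phase_lag_phi=phi, groups=groups,
                               alpha_in_valid_range=in_range)
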