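"""Design of dynamically similar scaled oscillatory-flow experiments.

A scaled-up bench model of the aqueduct reproduces the dimensionless
pressure response of the human canal when the three governing groups match:

    a_E / L_E = a_H / L_H,
    omega_E a_E^2 / nu_E = omega_H a_H^2 / nu_H   (equal Womersley number),
    Ls_E / L_E = Ls_H / L_H.

With those satisfied, measured pressures map between scales through

    <|dp|>_E / <|dp|>_H = (rho_E/rho_H) (nu_E/nu_H)^2 chi^-2,

where chi = L_E/L_H is the geometric scale factor.  Scaling up by chi ~ 10
with a glycerol-water working fluid raises the few-Pa physiological signal
into the hundreds-of-Pa range of ordinary differential transducers.

The glycerol-water property model combines the Cheng (2008) dynamic
viscosity correlation with a volume-fraction-weighted density built from
temperature-dependent component densities.  The three mixtures used on the
reference rig (84/16, 80/20, 74/26 by volume at 21.5 degC) are shipped as
exact lookup overrides so that their published properties are reproduced
verbatim; the correlation fills the continuum (expected accuracy on nu of
roughly +/-5%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .core import (CanalGeometry, FluidProperties, OscillationSpec,
                   womersley_number, _require_positive)
from .units import omega_to_bpm

__all__ = [
    "PumpLimitWarning",
    "SimilarityWarning",
    "Configuration",
    "ScalingMap",
    "MixtureSpec",
    "FrequencyDesign",
    "SimilarityReport",
    "design_frequency",
    "similarity_check",
    "pressure_ratio",
    "map_pressure",
    "glycerol_water_properties",
    "design_report",
]

# Programmable-pump operating envelope of the reference rig.
PUMP_BPM_RANGE = (3.0, 200.0)
PUMP_STROKE_RANGE_ML = (0.0, 180.0)


class PumpLimitWarning(UserWarning):
    """A designed operating point falls outside the pump envelope."""


class SimilarityWarning(UserWarning):
    """Pressure mapping requested for configurations that are not similar."""


@dataclass(frozen=True)
class Configuration:
    """One complete flow configuration: canal, fluid and oscillation."""

    geometry: CanalGeometry
    fluid: FluidProperties
    oscillation: OscillationSpec

    @property
    def alpha(self) -> float:
        return womersley_number(self.geometry, self.fluid, self.oscillation.omega)

    @property
    def Ls_over_L(self) -> float:
        Ls = self.oscillation.stroke_volume_Vs / self.geometry.mean_area
        return Ls / self.geometry.length_L


@dataclass(frozen=True)
class ScalingMap:
    """Pairing of a human-scale and an experimental-scale configuration.

    ``chi`` is the geometric scale factor L_E/L_H (= a_E/a_H when the
    configurations are geometrically similar).
    """

    human: Configuration
    experiment: Configuration

    @property
    def chi(self) -> float:
        return self.experiment.geometry.length_L / self.human.geometry.length_L

    @property
    def pressure_ratio(self) -> float:
        """<|dp|>_E / <|dp|>_H = (rho_E/rho_H)(nu_E/nu_H)^2 chi^-2."""
        e, h = self.experiment.fluid, self.human.fluid
        return ((e.density_rho / h.density_rho)
                * (e.kin_viscosity_nu / h.kin_viscosity_nu) ** 2
                / self.chi**2)


@dataclass(frozen=True)
class FrequencyDesign:
    """Result of inverting the Womersley number for the drive frequency."""

    omega: float          # [rad/s]
    bpm: float            # raw beats per minute
    bpm_rounded: int      # nearest integer (ties away from zero)
    within_pump_limits: bool


@dataclass(frozen=True)
class SimilarityReport:
    """Relative residuals of the three similarity conditions."""

    aspect_ratio_residual: float
    womersley_residual: float
    stroke_ratio_residual: float
    tolerance: float
    passed: bool

    def residuals(self) -> dict[str, float]:
        return {"a_over_L": self.aspect_ratio_residual,
                "alpha": self.womersley_residual,
                "Ls_over_L": self.stroke_ratio_residual}


def design_frequency(alpha_target: float, geometry: CanalGeometry,
                     fluid: FluidProperties) -> FrequencyDesign:
    """Drive frequency achieving a target Womersley number.

    Inverts alpha = sqrt(omega a^2/nu): ``omega = alpha^2 nu / a^2``.  A
    result outside the pump envelope (3-200 BPM) is flagged with a warning,
    not an error, so the designer remains usable for other hardware.
    """
    _require_positive(alpha_target=alpha_target)
    omega = alpha_target**2 * fluid.kin_viscosity_nu / geometry.mean_radius_a**2
    bpm = omega_to_bpm(omega)
    in_range = PUMP_BPM_RANGE[0] <= bpm <= PUMP_BPM_RANGE[1]
    if not in_range:
        warnings.warn(
            f"designed frequency {bpm:.3g} BPM is outside the pump range "
            f"{PUMP_BPM_RANGE[0]:.0f}-{PUMP_BPM_RANGE[1]:.0f} BPM",
            PumpLimitWarning, stacklevel=2)
    # nearest integer, ties away from zero (0.5 rounds up)
    rounded = int(math.floor(bpm + 0.5))
    return FrequencyDesign(omega=omega, bpm=bpm, bpm_rounded=rounded,
                           within_pump_limits=in_range)


def _rel(lhs: float, rhs: float) -> float:
    return abs(lhs - rhs) / abs(rhs)


def similarity_check(mapping: ScalingMap, tolerance: float = 0.02) -> SimilarityReport:
    """Report the relative residuals of the three similarity conditions.

    Residuals compare a/L, alpha and Ls/L between the experimental and human
    configurations (experiment relative to human); the map passes when all
    three fall below ``tolerance`` (default 2%).
    """
    e, h = mapping.experiment, mapping.human
    r_aspect = _rel(e.geometry.aspect_ratio, h.geometry.aspect_ratio)
    r_alpha = _rel(e.alpha, h.alpha)
    r_stroke = _rel(e.Ls_over_L, h.Ls_over_L)
    passed = max(r_aspect, r_alpha, r_stroke) < tolerance
    return SimilarityReport(aspect_ratio_residual=r_aspect,
                            womersley_residual=r_alpha,
                            stroke_ratio_residual=r_stroke,
                            tolerance=tolerance, passed=passed)


def pressure_ratio(mapping: ScalingMap, check: bool = True) -> float:
    """Experimental-to-human pressure ratio (rho_E/rho_H)(nu_E/nu_H)^2 chi^-2.

    When ``check`` is true and the similarity conditions do not hold within
    the default 2% a :class:`SimilarityWarning` is attached — the ratio is
    then only formal.
    """
    if check and not similarity_check(mapping).passed:
        warnings.warn("similarity conditions are violated; pressure mapping "
                      "is not physically meaningful", SimilarityWarning,
                      stacklevel=2)
    return mapping.pressure_ratio


def map_pressure(measured_E: float, mapping: ScalingMap, check: bool = True) -> float:
    """Convert a measured experimental <|dp|> [Pa] to human scale [Pa]."""
    return measured_E / pressure_ratio(mapping, check=check)


# ---------------------------------------------------------------------------
# Glycerol-water mixture properties
# ---------------------------------------------------------------------------

#: Published properties of the three rig mixtures (volume fraction glycerol
#: -> (nu [m^2/s], rho [kg/m^3])), measured at 21.5 degC.
RIG_MIXTURES = {
    0.84: (10.5e-5, 1225.6),
    0.80: (6.82e-5, 1216.4),
    0.74: (3.83e-5, 1202.2),
}
_RIG_TEMPERATURE_C = 21.5

# Validity range adopted for the Cheng correlation.
_TEMP_RANGE_C = (0.0, 100.0)


@dataclass(frozen=True)
class MixtureSpec:
    """A glycerol-water mixture at a given temperature with its properties."""

    glycerol_volume_fraction: float
    temperature_C: float
    properties: FluidProperties


def _component_densities(T: float) -> tuple[float, float]:
    """(rho_glycerol, rho_water) [kg/m^3] at temperature T [degC]."""
    rho_g = 1277.0 - 0.654 * T
    rho_w = 1000.0 * (1.0 - abs((T - 4.0) / 622.0) ** 1.838)
    return rho_g, rho_w


def glycerol_water_properties(volume_fraction: float,
                              temperature_C: float = _RIG_TEMPERATURE_C,
                              exact_lookup: bool = True) -> FluidProperties:
    """Density and kinematic viscosity of a glycerol-water mixture.

    Parameters
    ----------
    volume_fraction : float
        Glycerol volume fraction in [0, 1].
    temperature_C : float
        Temperature in degC within [0, 100].
    exact_lookup : bool
        When true (default), the three rig mixtures at 21.5 degC return
        their published property values exactly; the correlation is used
        everywhere else.

    Notes
    -----
    Viscosity follows Cheng (2008), a mass-fraction power-law blend of the
    pure-component viscosities, accurate to a few percent over 0-100 degC;
    density is volume-fraction weighted with temperature-dependent component
    densities (sub-percent accuracy; volume change on mixing is neglected).
    """
    if not 0.0 <= volume_fraction <= 1.0:
        raise ValueError(f"volume_fraction must lie in [0, 1], got {volume_fraction!r}")
    if not _TEMP_RANGE_C[0] <= temperature_C <= _TEMP_RANGE_C[1]:
        raise ValueError(
            f"temperature {temperature_C!r} degC outside correlation validity "
            f"range {_TEMP_RANGE_C}")

    if exact_lookup and abs(temperature_C - _RIG_TEMPERATURE_C) < 0.25:
        for frac, (nu, rho) in RIG_MIXTURES.items():
            if abs(volume_fraction - frac) < 5e-4:
                return FluidProperties(density_rho=rho, kin_viscosity_nu=nu)

    T = temperature_C
    rho_g, rho_w = _component_densities(T)
    cv = volume_fraction
    rho = cv * rho_g + (1.0 - cv) * rho_w
    cm = cv * rho_g / rho  # mass fraction of glycerol

    # Cheng (2008): mu = mu_w^a * mu_g^(1-a), viscosities in mPa s
    mu_w = 1.790 * math.exp(-(1230.0 + T) * T / (36100.0 + 360.0 * T))
    mu_g = 12100.0 * math.exp((-1233.0 + T) * T / (9900.0 + 70.0 * T))
    a_coef = 0.705 - 0.0017 * T
    b_coef = (4.9 + 0.036 * T) * a_coef**2.5
    weight = 1.0 - cm + (a_coef * b_coef * cm * (1.0 - cm)
                         / (a_coef * cm + b_coef * (1.0 - cm)))
    mu = mu_w**weight * mu_g ** (1.0 - weight)  # [mPa s]
    nu = mu * 1e-3 / rho
    return FluidProperties(density_rho=rho, kin_viscosity_nu=nu)


def mixture_spec(volume_fraction: float,
                 temperature_C: float = _RIG_TEMPERATURE_C) -> MixtureSpec:
    """Convenience constructor bundling the mixture and its properties."""
    props = glycerol_water_properties(volume_fraction, temperature_C)
    return MixtureSpec(glycerol_volume_fraction=volume_fraction,
                       temperature_C=temperature_C, properties=props)


def design_report(mapping: ScalingMap,
                  Ls_over_L_range: tuple[float, float] = (0.5, 1.5),
                  mean_abs_Pi: float | None = None) -> dict[str, float | str | bool]:
    """Flat key-value design summary for a scaled experiment.

    Includes geometry, fluid, drive frequency, the stroke-volume range
    covering ``Ls_over_L_range`` and, when a dimensionless pressure level
    ``mean_abs_Pi`` is supplied, the expected experimental <|dp|> window.
    """
    e = mapping.experiment
    geom, fl, osc = e.geometry, e.fluid, e.oscillation
    report: dict[str, float | str | bool] = {
        "length_L_m": geom.length_L,
        "mean_radius_a_m": geom.mean_radius_a,
        "a_over_L": geom.aspect_ratio,
        "density_rho_kg_m3": fl.density_rho,
        "kin_viscosity_nu_m2_s": fl.kin_viscosity_nu,
        "omega_rad_s": osc.omega,
        "bpm": omega_to_bpm(osc.omega),
        "alpha": e.alpha,
        "chi": mapping.chi,
        "pressure_ratio": mapping.pressure_ratio,
        "similarity_passed": similarity_check(mapping).passed,
    }
    lo, hi = Ls_over_L_range
    area_L = geom.mean_area * geom.length_L
    report["Vs_min_m3"] = lo * area_L
    report["Vs_max_m3"] = hi * area_L
    vs_ml = (report["Vs_min_m3"] * 1e6, report["Vs_max_m3"] * 1e6)
    report["stroke_within_pump_limits"] = (
        PUMP_STROKE_RANGE_ML[0] <= vs_ml[0] and vs_ml[1] <= PUMP_STROKE_RANGE_ML[1])
    if mean_abs_Pi is not None:
        scale = fl.density_rho * osc.omega**2 * geom.length_L**2
        report["expected_dp_min_Pa"] = mean_abs_Pi * scale * lo
        report["expected_dp_max_Pa"] = mean_abs_Pi * scale * hi
    return report
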