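"""Unit conversions used at I/O boundaries.

All internal computation is strictly SI (m, s, kg, Pa, rad/s). Beats per
minute, millilitres and inches of water appear only in configuration files,
command-line flags and reports, and are converted here.
"""

from __future__ import annotations

import math

#: Pascals per inch of water column referenced to water at 4 degC
#: (the convention used on differential pressure transducer data sheets).
PA_PER_INH2O_4C = 249.082


def bpm_to_omega(bpm: float) -> float:
    """Convert a frequency in beats per minute to angular frequency [rad/s]."""
    return 2.0 * math.pi * bpm / 60.0


def omega_to_bpm(omega: float) -> float:
    """Convert an angular frequency [rad/s] to beats per minute."""
    return 60.0 * omega / (2.0 * math.pi)


def ml_to_m3(ml: float) -> float:
    """Convert millilitres to cubic metres."""
    return ml * 1e-6


def m3_to_ml(m3: float) -> float:
    """Convert cubic metres to millilitres."""
    return m3 * 1e6


def inh2o_to_pa(inh2o: float) -> float:
    """Convert inches of water (4 degC reference) to Pascals."""
    return inh2o * PA_PER_INH2O_4C


def mm_to_m(mm: float) -> float:
    """Convert millimetres to metres."""
    return mm * 1e-3
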