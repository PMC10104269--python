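import numpy as np
import pytest

from aqueductflow import (CanalGeometry, FluidProperties,
                          glycerol_water_properties)


@pytest.fixture(scope="session")
def real_geometry() -> CanalGeometry:
    """Scaled anatomically-derived canal: a = 1.3 cm, L = 15.8 cm."""
    return CanalGeometry(length_L=0.158, mean_radius_a=0.013)


@pytest.fixture(scope="session")
def human_geometry() -> CanalGeometry:
    """Human-scale aqueduct: a = 1.3 mm, L = 15.8 mm."""
    return CanalGeometry(length_L=0.0158, mean_radius_a=0.0013)


@pytest.fixture(scope="session")
def water() -> FluidProperties:
    return FluidProperties(density_rho=1000.0, kin_viscosity_nu=0.71e-6)


@pytest.fixture(scope="session")
def rig_fluids() -> dict[float, FluidProperties]:
    """The three bench glycerol-water mixtures keyed by volume fraction."""
    return {frac: glycerol_water_properties(frac) for frac in (0.84, 0.80, 0.74)}


@pytest.fixture(scope="session")
def mixture_for_alpha() -> dict[int, float]:
    """Mixture (volume fraction) used on the rig for each target alpha."""
    return {2: 0.84, 3: 0.80, 4: 0.74}
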