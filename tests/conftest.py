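import numpy as np
import pytest
from hypothesis import settings

from pathwayopt import (
    Landscape,
    make_design_space,
    synthetic_parts_library,
)


settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cube24():
    """The 3-gene, 24-level lycopene design grid."""
    return make_design_space(3, [24, 24, 24], ["crtE", "crtB", "crtI"])


@pytest.fixture(scope="session")
def small_space():
    return make_design_space(2, [3, 3])


@pytest.fixture(scope="session")
def tiny_cube():
    """A 6^3 grid small enough for exhaustive checks."""
    return make_design_space(3, [6, 6, 6])


@pytest.fixture(scope="session")
def unimodal_landscape(cube24):
    """A single broad interior bump: the easy ground-truth surface."""
    raw = Landscape(space=cube24, weights=(1.0,), centers=((0.55, 0.4, 0.65),),
                    widths=(0.45,), scale_factor=1.0)
    return Landscape(space=cube24, weights=raw.weights, centers=raw.centers,
                     widths=raw.widths, scale_factor=9.0 / raw.f_max)


@pytest.fixture(scope="session")
def parts_library(cube24):
    return synthetic_parts_library(cube24)
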