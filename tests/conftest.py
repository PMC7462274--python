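import numpy as np
import pytest

from scaffoldlab.geometry import (
    UnitCellSpec,
    calibrate_levelset,
)

TPMS = ["diamond", "gyroid", "schwarz-p", "fischer-koch-s", "f-rd"]
STRUTS = ["cube", "fd-cube", "octa"]
ALL_TOPOLOGIES = TPMS + STRUTS

# Table of published Gibson-Ashby exponents used by the mode classifier
# checks: (topology, n, mode).
PUBLISHED_GA_MODES = [
    ("diamond", 2.081, "bending"),
    ("gyroid", 2.131, "bending"),
    ("schwarz-p", 0.863, "stretching"),
    ("f-rd", 1.920, "bending"),
    ("fischer-koch-s", 2.322, "bending"),
    ("cube", 1.216, "stretching"),
    ("fd-cube", 1.361, "stretching"),
    ("octa", 1.474, "stretching"),
]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200901)


@pytest.fixture(scope="session")
def gyroid_half():
    """Gyroid cell calibrated to porosity 0.5 at a modest resolution."""
    C = calibrate_levelset("gyroid", 0.5, resolution=64)
    return UnitCellSpec("gyroid", C, resolution=64)


def spec_at(topology, porosity, resolution, cal_resolution=None):
    C = calibrate_levelset(
        topology, porosity, cal_resolution or resolution
    )
    return UnitCellSpec(topology, C, resolution=resolution)
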