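import numpy as np
import pytest

from qdri.mc import ChannelGeometry, LayeredMedium, ReflectanceLUT, run_mc
from qdri.optics import OpticalProperties, WavelengthGrid
from qdri.synthetic import PhantomOpticalModel, TissueForward

#: session baseline size: big enough for sub-percent channel statistics,
#: small enough to keep the suite inside its time budget
BASELINE_PHOTONS = 400_000
BASELINE_SEED = 7


@pytest.fixture(scope="session")
def baseline():
    """Zero-absorption transport baseline shared by the whole suite."""
    props = OpticalProperties([0.0], [10.0], [0.9], 1.37)
    return run_mc(LayeredMedium.semi_infinite(props), BASELINE_PHOTONS, BASELINE_SEED)


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def lut(baseline, geometry):
    return ReflectanceLUT(baseline, geometry)


@pytest.fixture(scope="session")
def grid2():
    """Analysis-band grid at 2 nm sampling (fit speed)."""
    return WavelengthGrid.analysis_band(step=2.0)


@pytest.fixture(scope="session")
def tissue_forward(lut, grid2):
    return TissueForward(lut, grid2)


@pytest.fixture(scope="session")
def phantom_model(grid2):
    return PhantomOpticalModel(grid2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
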