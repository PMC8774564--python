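import numpy as np
import pytest

from multit1 import (
    ComponentParameters,
    InversionRecoverySeries,
    VoxelSimulationSpec,
    forward_signal,
    make_ti_grid,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ti_grid_105():
    return make_ti_grid(105, 50.0, 3000.0)


@pytest.fixture(scope="session")
def voxel_spec():
    return VoxelSimulationSpec()


@pytest.fixture
def two_component_truth():
    return ComponentParameters(m0=np.array([60.0, 40.0]), t1_ms=np.array([700.0, 1400.0]))


@pytest.fixture
def noiseless_two_component_series(two_component_truth, ti_grid_105):
    mag = forward_signal(two_component_truth, ti_grid_105)
    return InversionRecoverySeries(ti_ms=ti_grid_105, magnitude=mag)
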