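import numpy as np
import pytest

from mlcsim import (BeamKernel, GridSpec, LeafGeometry, MLCParameters,
                    OffsetModel)


@pytest.fixture(scope="session")
def offset_model():
    return OffsetModel(0.0, 0.0, 0.0008)


@pytest.fixture(scope="session")
def zero_offset():
    return OffsetModel()


@pytest.fixture(scope="session")
def params():
    return MLCParameters(leaf_tip_width=0.3, transmission=0.025, tng_width=0.05)


@pytest.fixture(scope="session")
def geometry():
    return LeafGeometry.millennium120()


@pytest.fixture(scope="session")
def kernel():
    return BeamKernel()


@pytest.fixture
def small_grid():
    """24x24 cm at 2 mm, symmetric about the axis."""
    return GridSpec.centered(24.0, 24.0, 0.2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
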