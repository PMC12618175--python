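import numpy as np
import pytest

from fourdct.phantom import MotionModel, PhantomSpec
from fourdct.qametrics import SegmentationConfig
from fourdct.respsignal import GatingConfig, generate_sinusoid


@pytest.fixture(scope="session")
def seg():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def gating():
    return GatingConfig()


@pytest.fixture(scope="session")
def sphere_spec():
    """Clinical-resolution grid just large enough for the sphere plus
    +/- 1 cm travel (keeps render-heavy tests fast)."""
    return PhantomSpec(grid_shape=(64, 64, 56))


@pytest.fixture(scope="session")
def normal_trace():
    """The normal breathing pattern: 1 cm zero-to-peak, 4 s period."""
    return generate_sinusoid(10.0, 4.0, 30.0)


@pytest.fixture(scope="session")
def normal_motion(normal_trace):
    return MotionModel(normal_trace, axis="z")
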