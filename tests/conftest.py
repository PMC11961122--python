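import numpy as np
import pytest

from psmclock import (
    ClockParams,
    LifecycleParams,
    MotionParams,
    SimConfig,
    TissueGeometry,
)


@pytest.fixture
def geom():
    return TissueGeometry()


@pytest.fixture
def motion():
    return MotionParams()


@pytest.fixture
def clockp():
    return ClockParams()


@pytest.fixture
def lifep():
    return LifecycleParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def relaxed_state():
    """A fully initialized and relaxed default tissue, shared across tests."""
    from psmclock.engine import initialize_tissue

    return initialize_tissue(SimConfig(seed=7))
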