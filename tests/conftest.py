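import numpy as np
import pytest

from phaselge import (
    CardiacTiming,
    SequenceParams,
    plan_acquisition,
    two_sphere_phantom,
)


@pytest.fixture(scope="session")
def params_3t():
    """3T protocol: TR 5 ms, flip 3 deg, three evenly spaced offsets,
    two-beat recovery, 90% acquisition window."""
    return SequenceParams(tr_ms=5.0, flip_deg=3.0)


@pytest.fixture(scope="session")
def timing_60():
    return CardiacTiming.from_heart_rate(60.0, phase_duration_ms=50.0)


@pytest.fixture(scope="session")
def plan_60(params_3t, timing_60):
    return plan_acquisition(params_3t, timing_60)


@pytest.fixture(scope="session")
def small_phantom():
    """Two-sphere phantom small enough for per-test volume fits."""
    return two_sphere_phantom(shape=(48, 48), radius=8.0)


@pytest.fixture(scope="session")
def coarse_timing():
    """Few phases (300 ms resolution) to keep voxel-wise fits cheap."""
    return CardiacTiming.from_heart_rate(60.0, phase_duration_ms=300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
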