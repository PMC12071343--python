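import numpy as np
import pytest

from dualfiber.config import AnalysisConfig
from dualfiber.pipeline import analyze_session
from dualfiber.synth import (
    SimulationTruth,
    generate_looming_session,
    generate_social_session,
)


@pytest.fixture(scope="session")
def social_session():
    return generate_social_session(SimulationTruth.social(rng_seed=11))


@pytest.fixture(scope="session")
def looming_session():
    return generate_looming_session(SimulationTruth.looming(rng_seed=12))


@pytest.fixture(scope="session")
def social_result(social_session):
    return analyze_session(social_session, AnalysisConfig())


@pytest.fixture(scope="session")
def looming_result(looming_session):
    return analyze_session(looming_session, AnalysisConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trial(rel_time, dz, **kwargs):
    """Assemble a bare AlignedTrial for metric-level tests."""
    from dualfiber.align import AlignedTrial

    defaults = dict(
        subject_id="s0",
        sensor_id="rcamp2",
        event_type="sniff",
        trial_idx=0,
        onset_s=100.0,
        bout_duration_s=2.0,
        rel_time=np.asarray(rel_time, dtype=float),
        dz=np.asarray(dz, dtype=float),
    )
    defaults.update(kwargs)
    return AlignedTrial(**defaults)
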