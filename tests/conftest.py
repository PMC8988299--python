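import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spindlescore import ScoringParams, score_session
from spindlescore.synthetic import StatePlan, generate_session


@pytest.fixture(scope="session")
def mixed_session():
    """A short mixed session exercising every state (~11 min)."""
    plan = StatePlan(
        segments=(
            ("active", 30),
            ("freezing", 100),
            ("active", 140),
            ("quiet_wake", 50),
            ("sws", 200),
            ("rem", 45),
            ("active", 20),
            ("freezing", 80),
            ("active", 10),
        ),
        seed=11,
    )
    return generate_session(plan)


@pytest.fixture(scope="session")
def mixed_scoring(mixed_session):
    return score_session(
        mixed_session.cortical,
        mixed_session.hpc,
        mixed_session.speed,
        ScoringParams(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
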