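import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wordgraphs as wg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    # fresh, fixed stream per test: outcomes never depend on test order
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared by I/O and pipeline tests."""
    spec = wg.CohortSpec(n_control=12, n_psychosis=6, length=120, seed=7)
    return wg.generate_cohort(spec)


def make_transcript(tokens, subject_id="s1", group=wg.Group.CONTROL,
                    age=30.0, edu=12.0):
    return wg.Transcript(subject_id=subject_id, tokens=list(tokens),
                         group=group, age_years=age, education_years=edu)


@pytest.fixture
def transcript_factory():
    return make_transcript
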