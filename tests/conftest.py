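import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from peershift import (
    CohortSpec,
    DesignConfig,
    SubjectParams,
    TaskConfig,
    simulate_session,
)


@pytest.fixture(scope="session")
def design() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def subject() -> SubjectParams:
    return SubjectParams(
        subject_id="S001",
        age_baseline=16.0,
        mu_logk_true=-4.0,
        sigma_pref_true=0.8,
        sigma_ref_true=0.7,
        followup_interval=1.48,
    )


@pytest.fixture(scope="session")
def session(subject, task_config):
    """One fully simulated session, shared across read-only tests."""
    return simulate_session(subject, task_config, rng=123)


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    return CohortSpec(n_subjects=20)
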