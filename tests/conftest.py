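import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from pdsubtypes import CohortSpec, build_feature_matrix, default_profiles, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def cohort209():
    """One study-scale synthetic cohort (n matches the emulated study)."""
    return generate_cohort(CohortSpec(n=209, seed=1))


@pytest.fixture(scope="session")
def feature_matrix(cohort209):
    return build_feature_matrix(cohort209)


@pytest.fixture()
def base_record():
    """A single complete record, convenient for classifier edge cases."""
    return generate_cohort(CohortSpec(n=1, seed=42))[0]


@pytest.fixture()
def make_record(base_record):
    def _make(**overrides):
        return dataclasses.replace(base_record, **overrides)

    return _make
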