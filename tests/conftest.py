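import pytest
from hypothesis import settings

from dialysentinel.hr_features import extract_features
from dialysentinel.synthetic import generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Master seeds for the large shared cohorts (fixed so every run sees the
# same study conditions).
NORMAL_COHORT_SEED = 20260101
IDH_COHORT_SEED = 20260102
CLASSIFIER_COHORT_SEED = 20260103


def features_for(cases):
    return [extract_features(c.series)[0] for c in cases]


@pytest.fixture(scope="session")
def normal_cohort_1000():
    cases = generate_cohort(1000, 0, master_seed=NORMAL_COHORT_SEED)
    return cases, features_for(cases)


@pytest.fixture(scope="session")
def idh_cohort_1000():
    cases = generate_cohort(0, 1000, master_seed=IDH_COHORT_SEED)
    return cases, features_for(cases)


@pytest.fixture(scope="session")
def classifier_cohort_950():
    """530 normal + 420 IDH cases with their feature vectors."""
    cases = generate_cohort(530, 420, master_seed=CLASSIFIER_COHORT_SEED)
    return cases, features_for(cases)
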