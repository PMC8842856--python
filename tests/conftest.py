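import pytest

from copd_profiles import cohort as cohort_mod


@pytest.fixture(scope="session")
def default_config():
    return cohort_mod.default_config(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return cohort_mod.sample_cohort(default_config, seed=1)


@pytest.fixture(scope="session")
def longitudinal(default_config, default_cohort):
    return cohort_mod.sample_trajectories(
        default_config, cohort=default_cohort, seed=1, include_baseline=True
    )
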