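import pytest

from moodnpi import RunConfig, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced cohort for fast pipeline tests (12 participants, 18 NPIs)."""
    return SyntheticConfig(
        n_participants=12,
        days=20,
        records_per_day=5,
        n_second_assessments=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_run_config(small_config) -> RunConfig:
    return RunConfig(synthetic=small_config, n_trees=100, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale default cohort (23 participants, 38 assessments)."""
    return generate_cohort(SyntheticConfig(seed=1))
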