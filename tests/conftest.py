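import pytest

from wesconcord.synthetic_data import (
    SimulationConfig,
    simulate_cohort,
    simulate_cohort_in_memory,
)
from wesconcord.variant_concordance import CallSetCollection


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Five-case default-institution cohort used across test modules."""
    return SimulationConfig(seed=11, n_cases=5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort_in_memory(small_config)


@pytest.fixture(scope="session")
def small_collection(small_config, small_cohort) -> CallSetCollection:
    return CallSetCollection.from_calls(small_cohort.calls, roster=small_config.roster)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_config):
    """The same small cohort written to disk in the on-disk dialects."""
    out = tmp_path_factory.mktemp("cohort") / "cohort"
    simulate_cohort(small_config, out)
    return out
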