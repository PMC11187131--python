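import pytest

from mptlineup import fixtures
from mptlineup.lineup import default_plans, run_model_analysis
from mptlineup.mpt import FitOptions


@pytest.fixture(scope="session")
def exp1_analysis():
    groups, freqs = fixtures.fixture("exp1")
    return run_model_analysis(freqs, default_plans(), groups, FitOptions(seed=1))


@pytest.fixture(scope="session")
def exp2_analysis():
    groups, freqs = fixtures.fixture("exp2")
    return run_model_analysis(freqs, default_plans(), groups, FitOptions(seed=1))


@pytest.fixture(scope="session")
def exp1_data():
    return fixtures.fixture("exp1")


@pytest.fixture(scope="session")
def exp2_data():
    return fixtures.fixture("exp2")
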