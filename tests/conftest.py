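import pytest

from qofsmoke import datasets
from qofsmoke.synthetic_data import CohortConfig, generate_registry


@pytest.fixture(scope="session")
def example_records():
    """The five worked-example practices (A-E) for 2012/13."""
    return datasets.load_example_indicator_records()


@pytest.fixture(scope="session")
def default_registry():
    """One deterministic 215-practice synthetic registry plus its truth."""
    return generate_registry(CohortConfig(seed=11))


@pytest.fixture()
def small_config():
    return CohortConfig(n_practices=24, n_districts=4, seed=5)
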