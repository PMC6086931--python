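import pytest

from mhealth_cea import scale_up_model
from mhealth_cea import synthetic


@pytest.fixture(scope="session")
def table1_ledger():
    """The published 5-year cost table as a ledger fixture."""
    return synthetic.generate_cost_ledger()


@pytest.fixture(scope="session")
def year5_table():
    """Year-5 PSA parameter table and its ground truth."""
    return synthetic.generate_parameter_table(year=5, seed=0)


@pytest.fixture(scope="session")
def year5_model():
    """Decision model closure for the year-5 scale-up scenario."""
    return scale_up_model()
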