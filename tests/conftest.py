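import pytest
from hypothesis import settings

import ventcal

settings.register_profile("ci", deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1_records():
    return ventcal.load_table1()


@pytest.fixture(scope="session")
def table1_processed(table1_records):
    return ventcal.process_table(table1_records)
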