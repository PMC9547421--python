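import numpy as np
import pytest

from ringzf import domains


@pytest.fixture(scope="session")
def rule_table():
    return domains.default_rule_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
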