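import numpy as np
import pytest

import carp


@pytest.fixture(scope="session")
def standard_55_bank():
    return carp.standard_case_bank(5, 5)


@pytest.fixture(scope="session")
def standard_55_pmf(standard_55_bank):
    return carp.pattern_distribution(standard_55_bank, nodes=40)


@pytest.fixture(scope="session")
def uni_bank_8():
    """Unidimensional bank with mixed loadings, J=8."""
    return carp.sample_parameter_set(8, "uni", seed=20240913)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
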