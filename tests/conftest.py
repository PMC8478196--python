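import numpy as np
import pytest

from gammanet.cells import cell_params


@pytest.fixture()
def rng():
    # function-scoped: each test gets the same deterministic stream
    # regardless of which other tests ran before it
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rs_params():
    return cell_params("RS")


@pytest.fixture(scope="session")
def fs_params():
    return cell_params("FS")
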