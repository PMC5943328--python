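import numpy as np
import pytest

import tpms_scaffold as ts


@pytest.fixture(scope="session")
def unit_domain_64():
    return ts.Domain.cube(1.0, 64)


@pytest.fixture(scope="session")
def unit_domain_32():
    return ts.Domain.cube(1.0, 32)


@pytest.fixture(scope="session")
def gyroid():
    return ts.preset("G", cell_size=1.0)


@pytest.fixture(scope="session")
def random_points():
    rng = np.random.default_rng(20240917)
    return rng.uniform(-3.0, 3.0, size=(100, 3))
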