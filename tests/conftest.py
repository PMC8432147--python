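import numpy as np
import pandas as pd
import pytest

from selrecruit import CovariateSpec, PoolTable, generate_binary_pool, generate_normal_pool


@pytest.fixture(scope="session")
def binary_pool():
    """Two-binary-covariate pool of N=10000 from the default non-uniform joint."""
    return generate_binary_pool(10000, seed=1234)


@pytest.fixture(scope="session")
def normal_pool():
    """Single-covariate pool of N=10000 from Normal(0, 0.608^2)."""
    return generate_normal_pool(10000, seed=1234)


@pytest.fixture()
def skewed_binary_pool():
    """Single binary covariate, +1 proportion exactly 0.75, N=10000."""
    col = np.r_[np.ones(7500), -np.ones(2500)]
    return PoolTable(pd.DataFrame({"x": col}), [CovariateSpec("x", "binary")])
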