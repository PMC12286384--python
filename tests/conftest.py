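import numpy as np
import pytest

import sparseae as sa


@pytest.fixture(scope="session")
def default_sim():
    """One simulated dataset at the generator's default conditions."""
    return sa.simulate(sa.SimConfig(seed=11))


@pytest.fixture()
def tiny_expr():
    """A small hand-checkable expression matrix (4 samples x 5 genes)."""
    values = np.array(
        [
            [0.0, 1.0, 0.0, 0.0, 0.0],
            [2.0, 2.0, 0.0, 0.0, 0.0],
            [4.0, 3.0, 1.0, 0.0, 0.0],
            [6.0, 4.0, 2.0, 5.0, 0.0],
        ]
    )
    return sa.ExpressionMatrix(
        values, [f"g{i}" for i in range(5)], [f"s{i}" for i in range(4)]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
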