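import numpy as np
import pytest

from scmask.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 10-cell x 20-gene random integer count matrix."""
    values = rng.integers(0, 40, size=(10, 20)).astype(float)
    return ExpressionMatrix(
        values=values,
        cell_ids=[f"c{i}" for i in range(10)],
        gene_ids=[f"g{j}" for j in range(20)],
        stage="raw_counts",
    )
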