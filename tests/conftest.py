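import numpy as np
import pytest

from refval import ExpressionMatrix, SyntheticSpec, generate_dataset


@pytest.fixture
def toy_matrix():
    """Three genes spanning the three outcomes: a stable reference gene, a
    variable validation gene, and a gene with a zero library."""
    return ExpressionMatrix.from_values(
        ["g_ref", "g_val", "g_zero"],
        [f"c{i}" for i in range(1, 7)],
        [
            [64.0] * 6,
            [4.0, 1024.0, 4.0, 1024.0, 4.0, 1024.0],
            [64.0, 64.0, 64.0, 64.0, 64.0, 0.0],
        ],
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """Desk-scale synthetic benchmark: 600 noisy / 50 pass-all / 25
    stable-low genes, six libraries."""
    return generate_dataset(SyntheticSpec(group_quotas=(600, 50, 25), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
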