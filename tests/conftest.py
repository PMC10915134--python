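import numpy as np
import pandas as pd
import pytest

from pbmscore.io import ExpressionMatrix, GeneSignature


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x 3 samples with a known ordering in each sample."""
    data = pd.DataFrame(
        {
            "s1": [5.0, 1.0, 3.0, 2.0],
            "s2": [1.0, 2.0, 3.0, 4.0],
            "s3": [2.0, 2.0, 1.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def iid_matrix(rng):
    """300 genes x 200 samples of i.i.d. noise: every sample's ranking is an
    independent uniform permutation, so any fixed signature is 'randomly
    placed' in each sample."""
    vals = rng.normal(size=(300, 200))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i:03d}" for i in range(300)],
            columns=[f"s{i:03d}" for i in range(200)],
        )
    )


@pytest.fixture
def random_signature(rng):
    return GeneSignature(
        "rand20", frozenset(f"g{i:03d}" for i in rng.choice(300, 20, replace=False))
    )
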