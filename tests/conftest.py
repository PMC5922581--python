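import numpy as np
import pytest

import rpgp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 features x 4 samples with readable ids."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [0.5, -1.5, 2.5, -3.5],
            [10.0, 20.0, 30.0, 40.0],
        ]
    )
    return rpgp.ExpressionMatrix(
        values, ["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"]
    )


@pytest.fixture
def separable_dataset():
    """60 samples, 2 features, class = [x0 - x1 >= 0]: exactly expressible
    by a single (sub x0 x1) program."""
    gen = np.random.default_rng(7)
    X = gen.normal(size=(60, 2))
    y = (X[:, 0] - X[:, 1] >= 0).astype(int)
    return X, y
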