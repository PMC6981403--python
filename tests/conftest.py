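import numpy as np
import pandas as pd
import pytest

from prednet.encoding import CategoricalTable, one_hot_encode


@pytest.fixture
def small_table():
    """Three categorical variables, one with three levels."""
    df = pd.DataFrame(
        {
            "q1": ["A", "B", "A", "C", "B", "A", "C", "B"],
            "q2": ["yes", "no", "no", "yes", "yes", "no", "yes", "no"],
            "q3": ["x", "x", "y", "y", "x", "y", "x", "y"],
        }
    )
    return CategoricalTable(df)


@pytest.fixture
def small_encoded(small_table):
    return one_hot_encode(small_table)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_binary_problem(rng, n, p, signal=True):
    """A binary design matrix and target with optional planted signal."""
    X = (rng.random((n, p)) < 0.5).astype(float)
    if signal:
        logits = 1.5 * X[:, 0] - 1.0 * X[:, 1] + 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    else:
        y = (rng.random(n) < 0.5).astype(float)
    if y.min() == y.max():  # keep fixtures non-degenerate
        y[0] = 1 - y[0]
    return X, y
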