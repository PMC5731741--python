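import numpy as np
import pandas as pd
import pytest

from fgmd import CorrelationMatrix, ExpressionMatrix


def corr_from_pairs(ids, pair_values):
    """Build a CorrelationMatrix from explicit off-diagonal pair values."""
    n = len(ids)
    a = np.zeros((n, n))
    np.fill_diagonal(a, 1.0)
    index = {g: i for i, g in enumerate(ids)}
    for (g1, g2), v in pair_values.items():
        a[index[g1], index[g2]] = a[index[g2], index[g1]] = v
    return CorrelationMatrix(tuple(ids), a)


@pytest.fixture
def tiny_expr():
    """2 features x 3 samples with simple values."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
        index=["gA", "gB"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def worked_corr3():
    """The 3-gene network with off-diagonal values 0.2, 0.4, 0.6."""
    return corr_from_pairs(
        ["g1", "g2", "g3"], {("g1", "g2"): 0.2, ("g1", "g3"): 0.4, ("g2", "g3"): 0.6}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
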