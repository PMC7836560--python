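import numpy as np
import pandas as pd
import pytest

from cernet import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_counts():
    """5 genes x 4 samples with both groups represented."""
    genes = [f"g{i}" for i in range(5)]
    samples = ["t1", "t2", "n1", "n2"]
    counts = pd.DataFrame(
        [[10, 12, 5, 6], [100, 110, 95, 90], [0, 1, 0, 0],
         [50, 55, 60, 58], [7, 8, 9, 10]],
        index=genes, columns=samples,
    )
    groups = pd.Series(["tumour", "tumour", "normal", "normal"], index=samples)
    return CountMatrix(counts, groups)


@pytest.fixture
def nb_counts(rng):
    """A larger random NB matrix for normalization/DE tests."""
    n_g, n_s = 300, 10
    mu = np.exp2(rng.uniform(2, 9, n_g))
    counts = rng.negative_binomial(5, 5 / (5 + mu[:, None] * np.ones(n_s)))
    genes = [f"g{i}" for i in range(n_g)]
    samples = [f"s{i}" for i in range(n_s)]
    groups = pd.Series(["tumour"] * 5 + ["normal"] * 5, index=samples)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)
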