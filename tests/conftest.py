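import numpy as np
import pandas as pd
import pytest

from dystromon.core_io import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20211331)


@pytest.fixture
def small_cm(rng):
    """Random 50-gene x 10-sample count matrix with realistic abundances."""
    mu = 2.0 ** rng.normal(5, 1.5, 50)
    libs = rng.lognormal(np.log(5e5), 0.2, 10)
    counts = rng.poisson(mu[:, None] * libs[None, :] * 1e-6 * rng.gamma(10, 0.1, (50, 10)))
    return CountMatrix(tuple(f"g{i:03d}" for i in range(50)),
                       tuple(f"s{j}" for j in range(10)), counts)


@pytest.fixture
def tiny_meta():
    return pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(10)],
        "subject_id": [f"m{j}" for j in range(10)],
        "group": ["WT"] * 5 + ["mdx"] * 5,
        "timepoint": 30,
    })
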