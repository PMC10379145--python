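import numpy as np
import pandas as pd
import pytest

from uevrna import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230708)


def make_counts(values, feature_ids=None, sample_ids=None) -> CountMatrix:
    arr = np.asarray(values)
    feature_ids = feature_ids or [f"g{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=feature_ids, columns=sample_ids))


def random_counts(rng, n_features, n_samples, lam=20.0) -> CountMatrix:
    """Poisson-ish random counts with no all-zero samples and no sample that
    shares zero positive features with any other."""
    while True:
        arr = rng.poisson(lam, size=(n_features, n_samples))
        if (arr.sum(axis=0) > 0).all() and ((arr > 0).all(axis=1)).any():
            return make_counts(arr)


@pytest.fixture
def small_counts(rng) -> CountMatrix:
    return random_counts(rng, 30, 5)
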