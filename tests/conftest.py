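import numpy as np
import pytest

from gwopls import (
    CVConfig,
    default_benchmark_dataset,
    split_train_predict,
)

# Reduced-scale study conditions shared across the suite: the full
# 200-800 nm range at a 5 nm step (121 channels), 102 samples, light MCCV.
BENCH_STEP = 5.0
BENCH_CV_SPLITS = 12


@pytest.fixture(scope="session")
def bench_dataset():
    return default_benchmark_dataset(seed=7, step=BENCH_STEP)


@pytest.fixture(scope="session")
def bench_split(bench_dataset):
    return split_train_predict(bench_dataset, 0.5, seed=7)


@pytest.fixture()
def light_cv():
    return CVConfig(n_splits=BENCH_CV_SPLITS, seed=1)


@pytest.fixture(scope="session")
def toy_regression():
    """32 samples x 8 variables; columns 1, 4, 6 carry the signal, the
    rest are pure noise.  Response rescaled into the concentration range."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(32, 8))
    beta = np.zeros(8)
    beta[[1, 4, 6]] = [2.0, -1.5, 1.0]
    y = X @ beta + 0.3 * rng.normal(size=32)
    y = 50 + 5 * (y - y.mean()) / y.std()
    return X, y
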