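import numpy as np
import pytest

from structest.data_model import (
    GroupingVariable,
    IndicatorMatrix,
    auto_reverse_code,
    standardize,
)
from structest.synthetic_data import GeneratorConfig, generate_null_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_dataset_p2():
    """Moderate null dataset, d=5, p=2, for shared use across tests."""
    return generate_null_dataset(GeneratorConfig(d=5, N=2000, p=2, seed=42))


@pytest.fixture(scope="session")
def null_dataset_p4():
    return generate_null_dataset(GeneratorConfig(d=5, N=2000, p=4, seed=42))


@pytest.fixture(scope="session")
def prepared_p2(null_dataset_p2):
    data = null_dataset_p2
    return auto_reverse_code(standardize(data.X)), data.Z


@pytest.fixture(scope="session")
def prepared_p4(null_dataset_p4):
    data = null_dataset_p4
    return auto_reverse_code(standardize(data.X)), data.Z


def make_proportional_dataset(
    lam, scale, N=400, p=3, seed=3
) -> tuple[IndicatorMatrix, GroupingVariable]:
    """Dataset whose group-mean contrasts are *exactly* scale_w * lam.

    Within-level means are forced to gamma + lam * scale[w]; both tests'
    moment conditions are then exactly solvable.
    """
    lam = np.asarray(lam, float)
    scale = np.asarray(scale, float)
    d = lam.shape[0]
    rng_ = np.random.default_rng(seed)
    z = np.repeat(np.arange(1, p + 1), N // p + 1)[:N]
    X = rng_.standard_normal((N, d))
    for w in range(1, p + 1):
        mask = z == w
        X[mask] -= X[mask].mean(axis=0)
        X[mask] += lam[None, :] * scale[w - 1]
    return IndicatorMatrix(X), GroupingVariable(z, p=p)
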