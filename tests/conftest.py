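import numpy as np
import pytest

from hierlasso import SurvivalDataset


def random_dataset(
    rng: np.random.Generator,
    n: int = 30,
    p: int = 3,
    censor_frac: float = 0.3,
    ties: bool = False,
) -> SurvivalDataset:
    """Small unstructured survival dataset for unit tests."""
    time = rng.exponential(1.0, n) + 0.05
    if ties:
        time = np.round(time, 1) + 0.05
    event = (rng.random(n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[rng.integers(n)] = 1
    treatment = np.where(rng.random(n) < 0.5, 0.5, -0.5)
    X = rng.standard_normal((n, p))
    return SurvivalDataset(time, event, treatment, X)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_data(rng):
    return random_dataset(rng, n=40, p=3)


@pytest.fixture
def tied_data(rng):
    return random_dataset(rng, n=8, p=2, ties=True)
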