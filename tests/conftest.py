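import numpy as np
import pytest

from tsocclude import SignalTensor, SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    """8 samples x 60 timesteps x 3 signals of smooth quasi-periodic data."""
    X, _ = generate_dataset(SyntheticSpec(s=8, h=60, n=3, period=15.0, seed=7))
    return X


def random_tensor(rng, s=None, h=None, n=None) -> SignalTensor:
    s = s or int(rng.integers(1, 5))
    h = h or int(rng.integers(2, 40))
    n = n or int(rng.integers(1, 4))
    values = rng.normal(size=(s, h, n))
    return SignalTensor(values, tuple(f"s{j}" for j in range(n)))
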