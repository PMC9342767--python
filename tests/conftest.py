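import numpy as np
import pytest

from fedseal.crypto.bundle import WeightBundle
from fedseal.crypto.codec import kgen


@pytest.fixture(scope="session")
def key():
    return kgen(256)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_bundle(rng, n_entries=4, max_dim=6):
    entries = {}
    for i in range(n_entries):
        ns = "base" if i % 2 == 0 else "head"
        rank = int(rng.integers(1, 4))
        shape = tuple(int(d) for d in rng.integers(1, max_dim + 1, size=rank))
        entries[f"{ns}/{i:03d}.layer.weight"] = rng.standard_normal(shape).astype(np.float32)
    return WeightBundle(entries)


@pytest.fixture()
def bundle(rng):
    return random_bundle(rng)
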