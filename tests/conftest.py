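import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _random_likelihoods(rng, k):
    """k random normalised likelihood/precision pairs."""
    from fepnet import normalize_likelihood

    out = []
    for _ in range(k):
        base = rng.uniform(0.05, 1.0, size=(2, 2))
        zeta = rng.uniform(0.1, 1.5)
        out.append((normalize_likelihood(base, zeta), zeta))
    return out

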