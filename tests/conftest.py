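import numpy as np
import pytest

import snm3f as sf


@pytest.fixture(scope="session")
def toy_noisy():
    """Four-task toy dataset at the study's 40% noise level."""
    return sf.generate(sf.toy_spec(seed=1))


@pytest.fixture(scope="session")
def toy_clean():
    """Noise-free variant of the toy design (exact factorization exists)."""
    return sf.generate(sf.toy_spec(seed=1, noise_fraction=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, S=6, T=3, M=4, P=2, N=2, K=3):
    """A small strictly-positive problem with balanced labels."""
    X = rng.uniform(0.1, 1.0, size=(S, T, M))
    labels = np.repeat(np.arange(1, K + 1), S // K)
    Wt = rng.uniform(0.1, 1.0, (T, P))
    Wt /= Wt.sum(axis=0)
    Ws = rng.uniform(0.1, 1.0, (N, M))
    Ws /= Ws.sum(axis=1, keepdims=True)
    A = rng.uniform(0.1, 1.0, (S, P, N))
    return X, labels, Wt, A, Ws
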