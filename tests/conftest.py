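import numpy as np
import pytest

from beebuzz import BuzzParams, SpectralConfig, extract_features, generate_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """40 worker (260 Hz) + 20 drone (200 Hz) synthetic 1-s clips, SNR 20 dB."""
    return generate_dataset(
        40,
        20,
        BuzzParams(snr_db=20.0),
        BuzzParams(fundamental_hz=200.0, snr_db=20.0),
        seed=123,
    )


@pytest.fixture(scope="session")
def burg_features(small_corpus):
    return extract_features(small_corpus, "burg")


@pytest.fixture(scope="session")
def music_features(small_corpus):
    return extract_features(small_corpus, "music")


@pytest.fixture(scope="session")
def ar1_signal():
    """AR(1) process x(n) = 0.9 x(n-1) + w(n), n = 10,000, fixed seed."""
    rng = np.random.default_rng(2024)
    w = rng.normal(size=10_000)
    x = np.empty_like(w)
    x[0] = w[0]
    for i in range(1, x.size):
        x[i] = 0.9 * x[i - 1] + w[i]
    return x
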