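import numpy as np
import pytest

import hybridmeta as hm


@pytest.fixture(scope="session")
def demo_pair() -> hm.StudyPair:
    """Two-group mean-difference pair: significant original t(78) = 2.211
    with n = 40/40, replication t(158) = 1.040 with n = 80/80."""
    return hm.StudyPair(
        original=hm.g_from_t(2.211, 40, 40),
        replication=hm.g_from_t(1.040, 80, 80),
    )


@pytest.fixture(scope="session")
def correlation_pair() -> hm.StudyPair:
    """Correlation pair on the Fisher-z scale with a clearly significant
    original (r = .45, n = 55) and a weaker replication (r = .10, n = 96)."""
    return hm.StudyPair(
        original=hm.z_from_r(0.45, 55),
        replication=hm.z_from_r(0.10, 96),
        backend=hm.Backend.NORMAL,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def simulated_pairs() -> list:
    """A reproducible batch of Fisher-z pairs spanning both hybrid-R
    branches and a range of effect magnitudes."""
    pairs = []
    for seed in range(12):
        pairs.append(hm.simulate_pair(0.3, 31, 55, seed=1000 + seed))
        pairs.append(hm.simulate_pair(0.0, 55, 31, seed=2000 + seed))
    return pairs
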