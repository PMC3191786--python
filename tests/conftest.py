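import numpy as np
import pytest

from multicsp.trials import CovariancePair


def rand_spd(d: int, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
    A = rng.standard_normal((d, d))
    return A @ A.T + jitter * d * np.eye(d)


def rand_cov_pair(d: int, rng: np.random.Generator) -> CovariancePair:
    return CovariancePair(rand_spd(d, rng), rand_spd(d, rng))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
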