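import numpy as np
import pytest

from bma_vision import StudyTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_table():
    """Factory for small random study tables with a known linear signal."""

    def _make(seed=0, n=40, s=3, beta=None, noise_sd=1.0, names=None):
        gen = np.random.default_rng(seed)
        x = gen.normal(0.0, 1.0, size=(n, s)) + gen.normal(5.0, 1.0, size=s)
        if beta is None:
            beta = np.zeros(s)
        y = 4.6 + x @ np.asarray(beta) + gen.normal(0.0, noise_sd, size=n)
        if names is None:
            names = tuple(f"x{j}" for j in range(s))
        return StudyTable(outcome=y, covariates=x, names=names)

    return _make
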