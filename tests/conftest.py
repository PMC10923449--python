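import numpy as np
import pytest

from prabheat import ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    """The reference fractional study set (Qm = 1.2, Q0 = 1)."""
    return ModelParams(alpha=0.8, beta=0.4, gamma=0.6, wp=0.2,
                       a0=1.0, b0=0.5, Q0=1.0, Qm=1.2)


@pytest.fixture
def classical_params() -> ModelParams:
    """Classical Fourier limit beta = gamma = 0 of the same study."""
    return ModelParams(alpha=1.0, beta=0.0, gamma=0.0, wp=0.0,
                       a0=1.0, b0=0.5, Q0=1.0, Qm=1.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240308)
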