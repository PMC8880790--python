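import numpy as np
import pytest

from transgame import GameParams


@pytest.fixture
def params() -> GameParams:
    """Standard 100-player, 25-round configuration."""
    return GameParams()


@pytest.fixture
def small_params() -> GameParams:
    """Tiny configuration for exact/enumeration comparisons."""
    return GameParams(n_players=4, n_rounds=2, n_initial_purple=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
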