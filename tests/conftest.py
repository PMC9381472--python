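import numpy as np
import pytest

from hippolat.synthetic import PhantomConfig

#: TEs of the emulated six-echo T2-mapping protocol (ms).
SIX_TES = np.array([10.5, 21.0, 31.5, 42.0, 52.5, 63.0])


@pytest.fixture
def small_config() -> PhantomConfig:
    """Desk-scale phantom grid for fast per-test rendering."""
    return PhantomConfig(grid_shape=(32, 32, 16), noise_sd_relative=0.02)


@pytest.fixture
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(grid_shape=(32, 32, 16), noise_sd_relative=0.0)
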