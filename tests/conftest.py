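import numpy as np
import pytest

from dcepnms import AIFSpec, TimeGrid, synth_aif


@pytest.fixture(scope="session")
def grid():
    """A short acquisition grid (200 frames, injection at frame 15)."""

    return TimeGrid(np.arange(200) * (1.533 / 60.0), n_baseline=20)


@pytest.fixture(scope="session")
def aif(grid):
    return synth_aif(AIFSpec(t_inj=15 * float(grid.t[1])), grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
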