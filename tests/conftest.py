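import numpy as np
import pytest

from alchempart import SyntheticWindowSpec, gen_crooks_window
from alchempart.constants import DEFAULT_TEMPERATURE, rt

RT = rt(DEFAULT_TEMPERATURE)


@pytest.fixture
def small_work_set():
    """Tiny hand-written work sample pair used against arithmetic oracles."""
    from alchempart import WorkSampleSet

    return WorkSampleSet(
        forward=np.array([2.0, 3.0]),
        reverse=np.array([1.0, 2.5]),
        temperature=DEFAULT_TEMPERATURE,
    )


@pytest.fixture
def gaussian_window():
    """Moderate-overlap Crooks-consistent Gaussian window, fixed seed."""
    return gen_crooks_window(
        SyntheticWindowSpec(delta_g_true=10.0, sigma=2 * RT, n_samples=10_000, seed=42)
    )
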