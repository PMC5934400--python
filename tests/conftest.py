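import numpy as np
import pytest

from trajfit import TrajectoryEnsemble


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ensemble(rng):
    """Random 40-trajectory ensemble on 8 positive times."""
    times = np.arange(1.0, 9.0)
    values = rng.standard_normal((40, 8)) + 3.0 * times
    return TrajectoryEnsemble(times, values, "observable")
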