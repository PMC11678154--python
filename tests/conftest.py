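import numpy as np
import pytest

from spimdiff.fitting import FitConfig
from spimdiff.synth import make_preset, simulate_traces


@pytest.fixture(scope="session")
def noise_free_traces():
    """Noise-free model traces per preset, computed once per session."""
    cache = {}

    def get(name):
        if name not in cache:
            cache[name] = simulate_traces(make_preset(name), noise_free=True)
        return cache[name]

    return get


@pytest.fixture
def control_cfg():
    return FitConfig(t0_s=320.0)


def brute_force_half_time(params, x, t_max=6000.0, dt=0.01):
    """Independent tau_1/2 oracle: first crossing on a dense time grid."""
    from spimdiff.model import concentration

    t = np.arange(0.0, t_max, dt)
    c = concentration(params, x, t)
    below = np.nonzero(c <= 0.5 * c[0])[0]
    assert below.size, "oracle grid too short"
    return float(t[below[0]])
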