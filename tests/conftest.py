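import numpy as np
import pytest

from bpgrowth.growth_model import BPParameters, solve_curve
from bpgrowth.model_fitting import MassSeries

OBS_TIMES = tuple(float(t) for t in range(0, 15, 2))  # days 1,3,...,15 -> t = 0..14


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def logistic_params():
    """Logistic growth scaled to a blue-tit-like bird: hatch 1 g, asymptote 11 g."""
    return BPParameters(a=1.0, b=2.0, c=1.0, p=0.46, q=0.46 / 11.0)


@pytest.fixture
def noiseless_logistic_series(logistic_params):
    m = solve_curve(logistic_params, OBS_TIMES)
    return MassSeries(times=OBS_TIMES, masses=tuple(m))


@pytest.fixture
def noisy_logistic_series(logistic_params, rng):
    m = solve_curve(logistic_params, OBS_TIMES)
    noisy = m * np.exp(rng.normal(0.0, 0.05, m.size))
    return MassSeries(times=OBS_TIMES, masses=tuple(noisy))
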