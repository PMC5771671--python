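import numpy as np
import pytest

from fateplane import find_fixed_points, get_preset


@pytest.fixture(scope="session")
def main_params():
    return get_preset("main")


@pytest.fixture(scope="session")
def main_fps(main_params):
    """Attractor/saddle geometry of the shipped main parameter set."""
    return find_fixed_points(main_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
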