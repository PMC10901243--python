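import numpy as np
import pytest

from fiberpol import depolarizer_diag, linear_diattenuator, linear_retarder


@pytest.fixture
def rng():
    return np.random.default_rng(20240228)


def random_factors(rng, n, d_max=0.9, depol_min=0.1):
    """Random generation parameters and composed depolarizer@retarder@diattenuator
    matrices for round-trip tests."""
    params = {
        "depol": rng.uniform(depol_min, 1.0, (n, 3)),
        "delta": rng.uniform(5.0, 175.0, n),
        "theta": rng.uniform(0.0, 180.0, n),
        "D": rng.uniform(0.0, d_max, n),
        "alpha": rng.uniform(0.0, 180.0, n),
    }
    M = (
        depolarizer_diag(params["depol"][:, 0], params["depol"][:, 1], params["depol"][:, 2])
        @ linear_retarder(params["delta"], params["theta"])
        @ linear_diattenuator(params["D"], params["alpha"])
    )
    return params, M


@pytest.fixture
def random_physical_image(rng):
    """A 16x16 image of random physically composed Mueller matrices."""
    _, M = random_factors(rng, 256)
    return M.reshape(16, 16, 4, 4)
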