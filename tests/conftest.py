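import numpy as np
import pytest

import netlandscape as nl


@pytest.fixture(scope="session")
def default_grid_result():
    """One full default grid run (3 models x 3 conditions x 3 multipliers,
    20 seeds), shared across tests that inspect different aspects of it."""
    return nl.run_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ising(rng, n=4, encoding="01", scale=1.0):
    """Random (not sign-constrained) Ising parameters for property tests."""
    w = rng.normal(scale=scale, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return nl.IsingParameters(encoding=encoding, tau=rng.normal(scale=scale, size=n),
                              omega=w)
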