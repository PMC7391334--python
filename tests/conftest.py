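import numpy as np
import pytest

from hoopoeipm.params import TrueParams
from hoopoeipm import synthdata


@pytest.fixture(scope="session")
def small_params():
    """A small, quick scenario: three habitats, modest populations."""
    return TrueParams(
        init_N=np.array([[6, 10, 4]] * 3),
        mark_rate_juv=0.3,
        mark_rate_adult=0.1,
    )


@pytest.fixture(scope="session")
def small_bundle(small_params):
    bundle, traj = synthdata.simulate_bundle(small_params, n_years=10, seed=42)
    return bundle, traj


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_msparams(rng, n_int, time_varying=True):
    """Valid random multistate parameters for oracle comparisons."""
    from hoopoeipm.cmr import MSParams

    shape = (3, n_int) if time_varying else (3,)
    return MSParams(
        s1=rng.uniform(0.05, 0.95, shape),
        s2=rng.uniform(0.05, 0.95, shape),
        psi1=rng.dirichlet(np.ones(3), 3),
        psi2=rng.dirichlet(np.ones(3), 3),
        p=rng.uniform(0.05, 0.95, n_int),
    )
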