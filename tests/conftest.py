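import numpy as np
import pytest

from alphacrit import crosnet


@pytest.fixture(scope="session")
def baseline_cfg():
    return crosnet.NetworkConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny 5x5 lattice with a raised background rate for fast, active runs."""
    from dataclasses import replace

    return replace(
        crosnet.NetworkConfig(),
        n_units=25,
        neighborhood=3,
        p0_exc=5e-3,
        p0_inh=5e-3,
    )


@pytest.fixture(scope="session")
def warm_kernel(small_cfg):
    """Trigger numba compilation once per session on a tiny problem."""
    conn = crosnet.build_connectome(small_cfg, 0)
    crosnet.simulate(conn, small_cfg, 0.05, 0)
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
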