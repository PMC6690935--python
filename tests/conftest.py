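import numpy as np
import pytest

from nichesim import fixtures as fx
from nichesim.config import VesselConfig


@pytest.fixture(scope="session")
def random_mesh():
    """Medium random-radius perfused mesh shared across read-only tests."""
    import nichesim as ns
    cfg = VesselConfig(nx=7, ny=7, nz=5)
    net = ns.build_capillary_mesh(cfg, seed=11)
    ns.compute_flow(net)
    ns.propagate_hematocrit(net, cfg.inlet_hematocrit)
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cell_ball_100():
    return fx.cell_ball(seed=5, n=100)
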