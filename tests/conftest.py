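import numpy as np
import pytest

from channelnet import AgentState, ModelParams, SimConfig


@pytest.fixture
def params():
    """Plain interaction parameters with motility couplings disabled."""
    return ModelParams(
        f_base=1.0, alpha=10.0, r_cut=30.0, mobility=1.0,
        align_rate=1.0, heading_align=0.0, mech_gain=0.0,
        noise_eta=0.0, leader_factor=2.0, dt=0.1,
    )


@pytest.fixture
def small_config():
    """A fast-to-run simulation configuration for integration tests."""
    return SimConfig(
        domain_size=200.0, n_agents=25, n_steps=200, record_every=10, seed=11,
    )


def make_agent(i, x, y, heading=0.0, radius=4.0, role="follower", speed=0.02):
    return AgentState(
        id=i, position=np.array([x, y], float), heading=heading,
        radius=radius, role=role, speed=speed,
    )


@pytest.fixture
def agent_factory():
    return make_agent
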