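import numpy as np
import pytest

from plastnet.topology import (
    ROLE_HIDDEN,
    ROLE_INPUT,
    ROLE_OUTPUT,
    NetworkSpec,
    TopologyConfig,
)


def make_net(n_inputs, n_hidden, edges, positions=None, inhibitory=None):
    """Build a small hand-wired network for dynamics tests.

    Neurons are ordered inputs, hidden, output (last).  ``edges`` is a
    list of (pre, post, weight) triplets.
    """
    n = n_inputs + n_hidden + 1
    roles = np.full(n, ROLE_HIDDEN, dtype=np.int8)
    roles[:n_inputs] = ROLE_INPUT
    roles[-1] = ROLE_OUTPUT
    if positions is None:
        positions = np.column_stack((np.arange(n, dtype=float), np.zeros(n)))
    inh = np.zeros(n, dtype=bool)
    if inhibitory is not None:
        inh[list(inhibitory)] = True
    edges = sorted(edges)
    cfg = TopologyConfig(n_hidden=max(n_hidden, 2), d0=1.0, out_degree=1, seed=0)
    return NetworkSpec(
        config=cfg,
        positions=np.asarray(positions, dtype=float),
        roles=roles,
        inhibitory=inh,
        syn_pre=np.array([e[0] for e in edges], dtype=np.int32),
        syn_post=np.array([e[1] for e in edges], dtype=np.int32),
        weights=np.array([e[2] for e in edges], dtype=float),
    )


@pytest.fixture
def two_neuron_chain():
    # input 0 -> hidden 1 -> output 2, unit weights
    return make_net(1, 1, [(0, 1, 1.0), (1, 2, 1.0)])
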