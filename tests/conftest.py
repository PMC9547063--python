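"""Shared fixtures: toy networks and a session-scoped synthetic network."""

import numpy as np
import pytest

from capnet.network import MicrovascularNetwork, assign_branch_orders
from capnet.solver import assign_default_boundary_pressures
from capnet.synthetic import GeneratorConfig, generate_cortical_mvn, generate_toy
from capnet.transport import steady_plasma_flow


def build_network(nodes, edges):
    """nodes: (id, x, y, z, is_boundary); edges: (id, a_id, b_id, D, L, type)."""
    node_ids = np.array([n[0] for n in nodes], dtype=np.int64)
    idx = {int(i): k for k, i in enumerate(node_ids)}
    return MicrovascularNetwork(
        node_ids=node_ids,
        positions=np.array([n[1:4] for n in nodes], dtype=np.float64),
        is_boundary=np.array([n[4] for n in nodes], dtype=bool),
        vessel_ids=np.array([e[0] for e in edges], dtype=np.int64),
        node_a=np.array([idx[e[1]] for e in edges], dtype=np.int64),
        node_b=np.array([idx[e[2]] for e in edges], dtype=np.int64),
        diameter=np.array([e[3] for e in edges], dtype=np.float64),
        length=np.array([e[4] for e in edges], dtype=np.float64),
        vessel_type=np.array([e[5] for e in edges], dtype=object),
    )


@pytest.fixture(scope="session")
def mvn():
    """Default synthetic cortical network with branch orders assigned."""
    net = generate_cortical_mvn(GeneratorConfig(seed=1))
    assign_branch_orders(net)
    return net


@pytest.fixture(scope="session")
def mvn_bc(mvn):
    return assign_default_boundary_pressures(mvn)


@pytest.fixture(scope="session")
def mvn_plasma(mvn, mvn_bc):
    """Cheap steady plasma baseline on the session network."""
    return steady_plasma_flow(mvn, mvn_bc)


@pytest.fixture()
def single_tube():
    return generate_toy("single_tube", diameter=6.0, length=500.0)


@pytest.fixture()
def divergent_y():
    return generate_toy("divergent_Y")


@pytest.fixture()
def two_path_loop():
    return generate_toy("two_path_loop")


@pytest.fixture(scope="session")
def honeycomb():
    net = generate_toy("honeycomb_sheet", rows=8, cols=8)
    assign_branch_orders(net)
    return net
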