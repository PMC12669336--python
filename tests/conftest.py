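import numpy as np
import pytest

from ngvu.micro3d1d import CapillaryGraph
from ngvu.synapse.params import load_params
from ngvu.nvc.params import load_nvc_params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def syn_params():
    return load_params()


@pytest.fixture
def nvc_params():
    return load_nvc_params()


@pytest.fixture
def straight_vessel_graph():
    """10-node straight capillary along x in a 150x160x140 box."""
    n = 10
    x = np.linspace(5.0, 145.0, n)
    nodes = np.column_stack([x, np.full(n, 80.0), np.full(n, 70.0)])
    segments = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return CapillaryGraph(nodes=nodes, segments=segments,
                          radii=np.full(n - 1, 4.0),
                          inlets=[0], outlets=[n - 1])


@pytest.fixture
def two_node_graph():
    nodes = np.array([[10.0, 80.0, 70.0], [140.0, 80.0, 70.0]])
    return CapillaryGraph(nodes=nodes, segments=np.array([[0, 1]]),
                          radii=np.array([4.0]), inlets=[0], outlets=[1])
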