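import networkx as nx
import pytest

from fnmotifs.network_io import POSITIVE, NEGATIVE, filter_degree, remove_intracomplex_edges
from fnmotifs.synthetic_fixtures import FixtureSpec, generate


def make_gi(edges):
    """Signed GI network from (u, v, sign) triples; scores are placeholders."""
    gi = nx.Graph()
    for u, v, sign in edges:
        gi.add_edge(u, v, sign=sign, score=1.0 if sign == POSITIVE else -1.0)
    return gi


@pytest.fixture
def triangle():
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def std_bundle():
    """The standard synthetic fixture (seed 1), shared across tests."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def enum_net(std_bundle):
    """The network actually searched: intra-complex edges and hubs removed."""
    net = remove_intracomplex_edges(std_bundle.ppi, std_bundle.complexes)
    return filter_degree(net, 50)
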