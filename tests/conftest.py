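import networkx as nx
import pytest

from ppinet import PPINetwork, clean_network


def make_net(edges, name="test") -> PPINetwork:
    """Cleaned network from an iterable of (a, b) symbol pairs."""
    return clean_network(PPINetwork(graph=nx.Graph(list(edges)), name=name))


def random_connected_net(n: int, p: float, seed: int) -> PPINetwork:
    """Largest connected component of a G(n, p) graph with symbol labels."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    relabeled = nx.relabel_nodes(giant, {v: f"N{v:03d}" for v in giant})
    return clean_network(PPINetwork(graph=relabeled, name=f"gnp_{seed}"))


@pytest.fixture
def table2_net():
    from ppinet import table2_fixture

    return table2_fixture()


@pytest.fixture
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """Default-size synthetic input bundle plus its planted truth."""
    import ppinet as pp

    cfg = pp.SimulationConfig(seed=11)
    out = tmp_path_factory.mktemp("bundle")
    files = pp.write_bundle(cfg, out)
    net = pp.generate_parent_network(cfg)
    up, down = pp.planted_deg_sets(net, cfg)
    return {"cfg": cfg, "files": files, "net": net, "up": up, "down": down}
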