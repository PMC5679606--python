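import networkx as nx
import numpy as np
import pandas as pd
import pytest

from diffslc.io import InteractionRecord
from diffslc.network import EdgeWeights, edge_key
from diffslc.simulate import FixtureSpec, simulate_all


def toy_records():
    """Three yeast interactions (one duplicated) plus a self-loop and a non-yeast pair."""
    def rec(a, b, ta=4932, tb=4932):
        return InteractionRecord(
            interactor_a=a, interactor_b=b, taxon_a=ta, taxon_b=tb,
            xrefs_a=(("dip", a), ("uniprotkb", f"U_{a}")),
            xrefs_b=(("dip", b), ("uniprotkb", f"U_{b}")),
        )
    return [rec("A", "B"), rec("B", "A"), rec("A", "C"), rec("A", "A"),
            rec("A", "X", tb=9606)]


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture
def path3():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def star4():
    g = nx.star_graph(4)
    return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})


def random_graph(rng, n_max=50, p=0.15):
    n = int(rng.integers(4, n_max + 1))
    return nx.fast_gnp_random_graph(n, p, seed=int(rng.integers(2**31)))


@pytest.fixture(scope="session")
def small_fixture():
    """One coupled synthetic study small enough for every test to share."""
    return simulate_all(FixtureSpec(n_nodes=300, seed=42, n_satellites=4,
                                    unmapped_fraction=0.05, decoy_fraction=0.05))


def uniform_weights(net, coexpr=0.5, ecc=1.0):
    w = EdgeWeights()
    for u, v in net.edges():
        key = edge_key(u, v)
        w.coexpr[key] = coexpr
        w.ecc[key] = ecc
    return w
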