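import itertools

import pytest

from allomod import Module, StageNetwork


def clique_network(stage, *node_groups, extra_nodes=()):
    edges = []
    for nodes in node_groups:
        edges.extend(itertools.combinations(nodes, 2))
    return StageNetwork.from_edges(stage, edges, extra_nodes=extra_nodes)


def make_module(module_id, stage, edges, extra_nodes=()):
    from allomod.graph_io import canonical_edge

    nodes = set(extra_nodes)
    es = set()
    for a, b in edges:
        nodes |= {a, b}
        es.add(canonical_edge(a, b))
    return Module(module_id=module_id, stage_label=stage,
                  nodes=frozenset(nodes), edges=frozenset(es))


def clique_module(module_id, stage, nodes):
    return make_module(module_id, stage, itertools.combinations(sorted(nodes), 2))


@pytest.fixture
def k4_module():
    return clique_module("m1", "A", ["N1", "N2", "N3", "N4"])


@pytest.fixture
def helpers():
    class H:
        clique_network = staticmethod(clique_network)
        make_module = staticmethod(make_module)
        clique_module = staticmethod(clique_module)

    return H
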