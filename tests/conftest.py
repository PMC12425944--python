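import numpy as np
import pytest

from kgmine import Edge, KnowledgeGraph, Node, PredicateRegistry
from kgmine.fixtures import case_study_fixture
from kgmine.pipeline import build_graph


@pytest.fixture(scope="session")
def registry():
    return PredicateRegistry()


@pytest.fixture(scope="session")
def cs1_graph(tmp_path_factory):
    bundle = case_study_fixture("cs1_helminth_nafld")
    paths = bundle.write(tmp_path_factory.mktemp("cs1"))
    graph, dropped = build_graph(list(paths["configs"].values()), paths["resolver"])
    return graph, dropped


@pytest.fixture(scope="session")
def cs2_graph(tmp_path_factory):
    bundle = case_study_fixture("cs2_alistipes")
    paths = bundle.write(tmp_path_factory.mktemp("cs2"))
    graph, dropped = build_graph(list(paths["configs"].values()), paths["resolver"])
    return graph, dropped


def make_graph(edge_specs, categories=None):
    """Small-graph helper: edge_specs are (subject, predicate, object, attrs)."""
    categories = categories or {}
    g = KnowledgeGraph()
    for s, p, o, attrs in edge_specs:
        for curie in (s, o):
            if curie not in g.nodes:
                g.add_node(
                    Node(curie, categories.get(curie, "biolink:NamedThing"), curie)
                )
        g.add_edge(Edge(subject=s, predicate=p, object=o, attributes=dict(attrs),
                        provenance={"publication_id": attrs.get("pub", "pub1"),
                                    "table_id": "t1"}))
    return g


def random_strongly_connected_view(rng, max_nodes=5):
    """Seeded random weighted digraph containing a spanning cycle."""
    from kgmine.analytics import WeightedView

    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    arcs = {}
    perm = rng.permutation(n)
    for i in range(n):
        arcs[(nodes[perm[i]], nodes[perm[(i + 1) % n]])] = float(rng.uniform(0.5, 3))
    for _ in range(int(rng.integers(0, 2 * n))):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        if i != j:
            key = (nodes[i], nodes[j])
            arcs[key] = arcs.get(key, 0.0) + float(rng.uniform(0.5, 3))
    return WeightedView(nodes=nodes, arcs=arcs)
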