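"""Weighted views, centralities vs. independent oracles, rankings, summaries."""

import itertools
import math

import numpy as np
import pytest

from kgmine.analytics import (
    CENTRALITY_METHODS,
    ConvergenceError,
    WeightedView,
    centrality,
    metagraph,
    publication_summary,
    rank_taxa_for_disease,
    to_weighted_view,
)
from kgmine.graph import PredicateRegistry

from conftest import make_graph, random_strongly_connected_view


# ---------------------------------------------------------------------------
# Independent oracles (brute force / dense linear algebra)


def oracle_betweenness(view):
    """Exhaustive simple-path enumeration under distances 1/w."""
    nodes = view.nodes
    adj = {}
    for (u, v), w in view.arcs.items():
        adj.setdefault(u, []).append((v, 1.0 / w))
    bc = {u: 0.0 for u in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = []

        def dfs(u, dist, visited, path):
            if u == t:
                paths.append((dist, list(path)))
                return
            for v, d in adj.get(u, []):
                if v not in visited:
                    visited.add(v)
                    path.append(v)
                    dfs(v, dist + d, visited, path)
                    path.pop()
                    visited.remove(v)

        dfs(s, 0.0, {s}, [s])
        if not paths:
            continue
        best = min(d for d, _ in paths)
        shortest = [p for d, p in paths if math.isclose(d, best, rel_tol=1e-12)]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def oracle_eigenvector(view):
    A = view.adjacency()
    w, V = np.linalg.eig(A.T)
    real = [i for i in range(len(w)) if abs(w[i].imag) < 1e-9]
    i0 = max(real, key=lambda i: w[i].real)
    vec = V[:, i0].real
    vec = vec * np.sign(vec[np.argmax(np.abs(vec))])
    return float(w[i0].real), dict(zip(view.nodes, vec / np.max(vec)))


def oracle_katz(view, alpha_fraction=0.8):
    lam, eig = oracle_eigenvector(view)
    n = view.n
    A = view.adjacency()
    beta = np.array([eig[u] for u in view.nodes])
    x = np.linalg.solve(np.eye(n) - (alpha_fraction / lam) * A.T, beta)
    return dict(zip(view.nodes, x))


def oracle_pagerank(view, damping=0.85):
    A = view.adjacency()
    n = view.n
    out = A.sum(axis=1)
    P = np.zeros((n, n))
    for i in range(n):
        P[i] = A[i] / out[i] if out[i] > 0 else 1.0 / n
    pi = np.linalg.solve(np.eye(n) - damping * P.T, (1 - damping) / n * np.ones(n))
    pi /= pi.sum()
    return dict(zip(view.nodes, pi))


ORACLES = {
    "betweenness": oracle_betweenness,
    "eigenvector": lambda v: oracle_eigenvector(v)[1],
    "katz": oracle_katz,
    "pagerank": oracle_pagerank,
}


# ---------------------------------------------------------------------------


def sym_view(pairs, w=1.0):
    arcs = {}
    for a, b in pairs:
        arcs[(a, b)] = w
        arcs[(b, a)] = w
    nodes = sorted({x for p in pairs for x in p})
    return WeightedView(nodes=nodes, arcs=arcs)


class TestWeightedView:
    def test_symmetric_edge_contributes_both_directions(self, registry):
        g = make_graph([("X:a", "biolink:correlated_with", "X:b", {"score": 2.0})])
        view = to_weighted_view(g, registry)
        assert view.arcs == {("X:a", "X:b"): 2.0, ("X:b", "X:a"): 2.0}

    def test_parallel_directed_edges_sum(self, registry):
        g = make_graph([
            ("X:a", "biolink:affects", "X:b", {"score": 1.0}),
            ("X:a", "biolink:affects", "X:b", {"score": 3.0}),
        ])
        view = to_weighted_view(g, registry)
        assert view.arcs == {("X:a", "X:b"): 4.0}

    def test_mixed_graph_arc_count(self, registry):
        specs = [
            ("X:a", "biolink:correlated_with", "X:b", {"score": 1.0}),
            ("X:b", "biolink:associated_with", "X:c", {"score": 1.0}),
            ("X:c", "biolink:correlated_with", "X:d", {"score": 1.0}),
            ("X:a", "biolink:affects", "X:c", {"score": 1.0}),
            ("X:d", "biolink:affects", "X:b", {"score": 1.0}),
        ]
        view = to_weighted_view(make_graph(specs), registry)
        assert len(view.arcs) == 8  # 2*3 symmetric + 2 directed

    def test_unscored_edge_is_validation_failure(self, registry):
        g = make_graph([("X:a", "biolink:affects", "X:b", {})])
        with pytest.raises(ValueError):
            to_weighted_view(g, registry)


class TestClosedForms:
    def test_four_cycle_pagerank_is_quarter_each(self):
        view = sym_view([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        scores = centrality(view, "pagerank").scores
        for v in scores.values():
            assert v == pytest.approx(0.25, abs=1e-9)
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_path_graph_betweenness_middle_carries_both_pairs(self):
        view = sym_view([("A", "B"), ("B", "C")])
        scores = centrality(view, "betweenness").scores
        # unnormalized directed counting: A->C and C->A both pass through B
        assert scores == {"A": 0.0, "B": 2.0, "C": 0.0}

    def test_small_katz_matches_direct_solve(self):
        rng = np.random.default_rng(17)
        view = random_strongly_connected_view(rng, max_nodes=5)
        got = centrality(view, "katz").scores
        want = oracle_katz(view)
        for u in view.nodes:
            assert got[u] == pytest.approx(want[u], abs=1e-8)

    def test_nilpotent_adjacency_fails_for_spectral_methods(self):
        view = WeightedView(nodes=["A", "B"], arcs={("A", "B"): 1.0})
        with pytest.raises(ConvergenceError):
            centrality(view, "eigenvector")

    def test_unknown_method_rejected(self):
        view = sym_view([("A", "B")])
        with pytest.raises(ValueError):
            centrality(view, "closeness")


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", CENTRALITY_METHODS)
    def test_random_digraphs_match_oracles(self, method):
        rng = np.random.default_rng(100)
        for _ in range(25):
            view = random_strongly_connected_view(rng, max_nodes=5)
            got = centrality(view, method).scores
            want = ORACLES[method](view)
            for u in view.nodes:
                assert got[u] == pytest.approx(want[u], abs=1e-8), (method, view.arcs)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        view = random_strongly_connected_view(rng, max_nodes=5)
        scaled = WeightedView(
            nodes=view.nodes,
            arcs={k: 7.5 * w for k, w in view.arcs.items()},
        )
        for method in CENTRALITY_METHODS:
            a = centrality(view, method).scores
            b = centrality(scaled, method).scores
            rank_a = sorted(view.nodes, key=lambda u: a[u])
            rank_b = sorted(view.nodes, key=lambda u: b[u])
            assert rank_a == rank_b
            if method == "betweenness":
                for u in view.nodes:
                    assert a[u] == pytest.approx(b[u], abs=1e-9)


class TestRankTaxa:
    TAXON = "biolink:OrganismTaxon"
    DISEASE = "biolink:Disease"

    def categories(self, taxa, disease="MONDO:1"):
        cats = {t: self.TAXON for t in taxa}
        cats[disease] = self.DISEASE
        return cats

    def test_single_neighbor_selected_by_all_methods(self, registry):
        g = make_graph(
            [("MONDO:1", "biolink:associated_with", "TAX:1", {"score": 2.0})],
            categories=self.categories(["TAX:1"]),
        )
        res = rank_taxa_for_disease(g, "MONDO:1", registry)
        assert set(res["most_central"].values()) == {"TAX:1"}

    def test_planted_hub_wins_all_methods(self, registry):
        taxa = [f"TAX:{i}" for i in range(9)]
        hub = "TAX:0"
        specs = [("MONDO:1", "biolink:associated_with", hub, {"score": 10.0})]
        for i in range(1, 6):  # interlinked high-score cluster through the hub
            specs.append((hub, "biolink:correlated_with", f"TAX:{i}", {"score": 8.0}))
            specs.append(("MONDO:1", "biolink:associated_with", f"TAX:{i}",
                          {"score": 2.0}))
        for i, j in [(1, 2), (2, 3), (3, 4), (4, 5)]:
            specs.append((f"TAX:{i}", "biolink:correlated_with", f"TAX:{j}",
                          {"score": 1.0}))
        for i in range(6, 9):  # low-score periphery
            specs.append(("MONDO:1", "biolink:associated_with", f"TAX:{i}",
                          {"score": 0.5}))
        g = make_graph(specs, categories=self.categories(taxa))
        res = rank_taxa_for_disease(g, "MONDO:1", registry)
        assert set(res["most_central"].values()) == {hub}

    def test_structural_tie_broken_by_smaller_curie(self, registry):
        g = make_graph(
            [
                ("MONDO:1", "biolink:associated_with", "TAX:b", {"score": 3.0}),
                ("MONDO:1", "biolink:associated_with", "TAX:a", {"score": 3.0}),
            ],
            categories=self.categories(["TAX:a", "TAX:b"]),
        )
        res = rank_taxa_for_disease(g, "MONDO:1", registry)
        assert set(res["most_central"].values()) == {"TAX:a"}

    def test_no_taxon_neighbor_is_empty_result(self, registry):
        g = make_graph(
            [("MONDO:1", "biolink:associated_with", "CHEBI:1", {"score": 1.0})],
            categories={"MONDO:1": self.DISEASE,
                        "CHEBI:1": "biolink:SmallMolecule"},
        )
        res = rank_taxa_for_disease(g, "MONDO:1", registry)
        assert res["taxa"] == [] and res["most_central"] == {}

    def test_star_only_excludes_taxon_taxon_edges(self, registry):
        taxa = ["TAX:a", "TAX:b"]
        g = make_graph(
            [
                ("MONDO:1", "biolink:associated_with", "TAX:a", {"score": 1.0}),
                ("MONDO:1", "biolink:associated_with", "TAX:b", {"score": 1.0}),
                ("TAX:a", "biolink:correlated_with", "TAX:b", {"score": 9.0}),
            ],
            categories=self.categories(taxa),
        )
        full = rank_taxa_for_disease(g, "MONDO:1", registry)
        star = rank_taxa_for_disease(g, "MONDO:1", registry, star_only=True)
        # with the taxon-taxon edge removed the two taxa become symmetric
        assert star["tables"]["eigenvector"]["TAX:a"] == pytest.approx(
            star["tables"]["eigenvector"]["TAX:b"]
        )
        assert full["tables"]["eigenvector"]["TAX:a"] == pytest.approx(
            full["tables"]["eigenvector"]["TAX:b"]
        )


class TestSummaries:
    def test_bounds_formulas_at_n10(self, registry):
        specs = []
        nodes = [f"X:{i}" for i in range(10)]
        for a, b in zip(nodes, nodes[1:]):  # connected chain, 9 edges
            specs.append((a, "biolink:affects", b, {"pub": "pubA"}))
        g = make_graph(specs)
        (summary,) = publication_summary(g, registry)
        assert summary.n_nodes == 10
        assert summary.bounds == {
            "max_unique": 45, "min_connected": 9, "min_unconstrained": 5,
        }

    def test_duplicate_edges_counted_in_total_not_unique(self, registry):
        g = make_graph([
            ("X:a", "biolink:correlated_with", "X:b", {"pub": "pubA"}),
            ("X:b", "biolink:correlated_with", "X:c", {"pub": "pubA"}),
            ("X:a", "biolink:correlated_with", "X:b", {"pub": "pubA"}),
        ])
        (summary,) = publication_summary(g, registry)
        assert summary.n_edges_total == 3
        assert summary.n_edges_unique == 2
        assert summary.n_nodes == 3

    def test_per_publication_totals_sum_to_edge_count(self, registry):
        rng = np.random.default_rng(4)
        specs = []
        for _ in range(30):
            i, j = rng.integers(6), rng.integers(6)
            if i == j:
                continue
            specs.append(
                (f"X:{i}", "biolink:affects", f"X:{j}",
                 {"pub": f"pub{rng.integers(3)}"})
            )
        g = make_graph(specs)
        summaries = publication_summary(g, registry)
        assert sum(s.n_edges_total for s in summaries) == len(g.edges)

    def test_metagraph_counts_and_conservation(self, registry):
        g = make_graph(
            [
                ("TAX:1", "biolink:affects", "MONDO:1", {}),
                ("TAX:2", "biolink:affects", "MONDO:1", {}),
            ],
            categories={"TAX:1": "biolink:OrganismTaxon",
                        "TAX:2": "biolink:OrganismTaxon",
                        "MONDO:1": "biolink:Disease"},
        )
        meta = metagraph(g, registry)
        assert meta.class_counts == {"biolink:OrganismTaxon": 2,
                                     "biolink:Disease": 1}
        assert meta.arc_counts == {
            ("biolink:OrganismTaxon", "biolink:affects", "biolink:Disease"): 2
        }

    def test_symmetric_arc_canonicalized_by_class_order(self, registry):
        g = make_graph(
            [("UniProtKB:1", "biolink:correlated_with", "CHEBI:1", {})],
            categories={"UniProtKB:1": "biolink:Protein",
                        "CHEBI:1": "biolink:SmallMolecule"},
        )
        meta = metagraph(g, registry)
        assert list(meta.arc_counts) == [
            ("biolink:Protein", "biolink:correlated_with", "biolink:SmallMolecule")
        ]

    def test_random_graph_arc_counts_sum_to_edges(self, registry):
        rng = np.random.default_rng(8)
        cats = ["biolink:OrganismTaxon", "biolink:Disease", "biolink:Gene"]
        preds = ["biolink:affects", "biolink:correlated_with"]
        specs, categories = [], {}
        for _ in range(40):
            i, j = rng.integers(8), rng.integers(8)
            if i == j:
                continue
            s, o = f"X:{i}", f"X:{j}"
            categories.setdefault(s, cats[i % 3])
            categories.setdefault(o, cats[j % 3])
            specs.append((s, preds[int(rng.integers(2))], o, {}))
        g = make_graph(specs, categories=categories)
        meta = metagraph(g, registry)
        assert sum(meta.arc_counts.values()) == len(g.edges)
        assert sum(meta.class_counts.values()) == len(g.nodes)
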