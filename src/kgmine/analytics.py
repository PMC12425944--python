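"""Weighted centrality analyses over the scored knowledge graph.

Edge scores act as affinity weights: a symmetric-predicate edge (correlated
with, associated with) contributes an arc in both directions, a directed
predicate (affects, treats) contributes one, and parallel same-direction
contributions sum — repeated independent evidence strengthens a tie. For
path-based betweenness, affinities convert to distances d = 1/w (a stronger
tie is a shorter hop); spectral measures (eigenvector, Katz, PageRank) use
the affinities directly.

Katz centrality solves x = alpha * A^T x + beta with alpha set to 80% of
the spectral convergence bound (alpha = 0.8 / lambda_max; the literal
0.8 * lambda_max diverges whenever lambda_max > 1) and beta_i set to node
i's eigenvector-centrality score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import networkx as nx
import numpy as np

from .graph import (
    Edge,
    KnowledgeGraph,
    PredicateRegistry,
    canonical_edge_key,
    unique_edge_count,
)

CENTRALITY_METHODS = ("betweenness", "eigenvector", "katz", "pagerank")

DEFAULT_PARAMS = {
    "katz_alpha_fraction": 0.8,
    "pagerank_damping": 0.85,
    "tolerance": 1e-10,
    "max_iter": 10_000,
}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class WeightedView:
    """Directed arc list with summed affinity weights and a node index."""

    nodes: list[str]
    arcs: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency; A[i, j] = weight of arc i -> j."""
        idx = {u: i for i, u in enumerate(self.nodes)}
        A = np.zeros((self.n, self.n))
        for (u, v), w in self.arcs.items():
            A[idx[u], idx[v]] = w
        return A

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for (u, v), w in self.arcs.items():
            G.add_edge(u, v, weight=w, dist=1.0 / w)
        return G


@dataclass
class CentralityReport:
    method: str
    parameters: dict[str, Any]
    scores: dict[str, float]


def to_weighted_view(
    graph: KnowledgeGraph, registry: PredicateRegistry
) -> WeightedView:
    """Build the weighted directed view from scored edges.

    Symmetric edges contribute both (u, v) and (v, u) at the edge's score;
    parallel same-direction contributions sum. Unscored edges are a
    validation failure — scoring comes first.
    """
    nodes = sorted(graph.nodes)
    view = WeightedView(nodes=nodes)
    for e in graph.edges:
        if e.score is None:
            raise ValueError(
                f"unscored edge {e.subject} -> {e.object}; score the graph first"
            )
        pairs = [(e.subject, e.object)]
        if registry.is_symmetric(e.predicate):
            pairs.append((e.object, e.subject))
        for u, v in pairs:
            view.arcs[(u, v)] = view.arcs.get((u, v), 0.0) + e.score
    return view


# ---------------------------------------------------------------------------
# Centralities


def _leading_eigenpair(
    A: np.ndarray, tol: float, max_iter: int
) -> tuple[float, np.ndarray]:
    """Perron pair of the nonnegative matrix A^T by shifted power iteration.

    Iterating (A^T + I) keeps the eigenvectors, shifts eigenvalues by +1,
    and breaks the oscillation that periodic graphs (e.g. even cycles)
    induce in plain power iteration.
    """
    n = A.shape[0]
    # a nonnegative adjacency is nilpotent iff its digraph is acyclic,
    # in which case lambda_max = 0 and spectral centralities are undefined
    if nx.is_directed_acyclic_graph(nx.from_numpy_array(A, create_using=nx.DiGraph)):
        raise ConvergenceError(
            "leading eigenvalue is zero (acyclic weighted view); "
            "eigenvector/Katz centrality undefined"
        )
    M = A.T + np.eye(n)
    x = np.full(n, 1.0 / n)
    for it in range(max_iter):
        y = M @ x
        norm = np.max(np.abs(y))
        if norm == 0:
            raise ConvergenceError("eigenvector: zero iterate (nilpotent adjacency)")
        y = y / norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise ConvergenceError(
            f"eigenvector: no convergence in {max_iter} iterations"
        )
    lam = float(x @ (A.T @ x) / (x @ x))
    if lam <= 0:
        raise ConvergenceError("leading eigenvalue is not positive")
    return lam, x / np.max(np.abs(x))


def _eigenvector_centrality(view: WeightedView, params: dict) -> dict[str, float]:
    A = view.adjacency()
    _, x = _leading_eigenpair(A, params["tolerance"], params["max_iter"])
    return dict(zip(view.nodes, x.tolist()))


def _katz_centrality(view: WeightedView, params: dict) -> dict[str, float]:
    A = view.adjacency()
    lam, eig = _leading_eigenpair(A, params["tolerance"], params["max_iter"])
    alpha = params["katz_alpha_fraction"] / lam
    beta = eig
    x = beta.copy()
    for it in range(params["max_iter"]):
        x_next = alpha * (A.T @ x) + beta
        if np.max(np.abs(x_next - x)) < params["tolerance"]:
            return dict(zip(view.nodes, x_next.tolist()))
        x = x_next
    raise ConvergenceError(f"katz: no convergence in {params['max_iter']} iterations")


def _pagerank(view: WeightedView, params: dict) -> dict[str, float]:
    G = view.to_networkx()
    try:
        pr = nx.pagerank(
            G,
            alpha=params["pagerank_damping"],
            weight="weight",
            tol=params["tolerance"],
            max_iter=params["max_iter"],
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise ConvergenceError(f"pagerank: {exc}") from exc
    return {u: float(s) for u, s in pr.items()}


def _betweenness(view: WeightedView, params: dict) -> dict[str, float]:
    G = view.to_networkx()
    bc = nx.betweenness_centrality(G, weight="dist", normalized=False)
    return {u: float(s) for u, s in bc.items()}


def centrality(
    view: WeightedView, method: str, params: dict | None = None
) -> CentralityReport:
    """Compute one of the four supported centralities over the view."""
    if method not in CENTRALITY_METHODS:
        raise ValueError(f"unknown centrality method: {method!r}")
    if view.n == 0:
        raise ValueError("empty view")
    p = {**DEFAULT_PARAMS, **(params or {})}
    fn = {
        "betweenness": _betweenness,
        "eigenvector": _eigenvector_centrality,
        "katz": _katz_centrality,
        "pagerank": _pagerank,
    }[method]
    return CentralityReport(method=method, parameters=p, scores=fn(view, p))


# ---------------------------------------------------------------------------
# Disease–taxon ranking


def rank_taxa_for_disease(
    graph: KnowledgeGraph,
    disease_curie: str,
    registry: PredicateRegistry,
    params: dict | None = None,
    star_only: bool = False,
    taxon_category: str = "biolink:OrganismTaxon",
) -> dict[str, Any]:
    """Most-central taxon directly connected to a disease, per method.

    Builds the subgraph induced on the disease and its direct taxon
    neighbors (taxon–taxon edges included unless ``star_only``), computes
    all four centralities, and per method selects the taxon — never the
    disease — with the maximal score; ties break to the lexicographically
    smaller CURIE.
    """
    if disease_curie not in graph.nodes:
        raise ValueError(f"disease node not in graph: {disease_curie}")
    taxa = set()
    for e in graph.edges:
        if e.subject == disease_curie:
            other = e.object
        elif e.object == disease_curie:
            other = e.subject
        else:
            continue
        if graph.nodes[other].category == taxon_category:
            taxa.add(other)
    if not taxa:
        return {"disease": disease_curie, "taxa": [], "most_central": {}, "tables": {}}

    keep = taxa | {disease_curie}
    sub = KnowledgeGraph(nodes={c: graph.nodes[c] for c in keep})
    for e in graph.edges:
        if e.subject in keep and e.object in keep:
            if star_only and disease_curie not in (e.subject, e.object):
                continue
            sub.edges.append(e)

    view = to_weighted_view(sub, registry)
    most_central: dict[str, str] = {}
    tables: dict[str, dict[str, float]] = {}
    for method in CENTRALITY_METHODS:
        report = centrality(view, method, params)
        taxon_scores = {c: report.scores[c] for c in sorted(taxa)}
        tables[method] = taxon_scores
        top = max(taxon_scores.values())
        # numerically indistinguishable scores tie; smaller CURIE wins
        tied = [
            c for c, s in taxon_scores.items()
            if math.isclose(s, top, rel_tol=1e-12, abs_tol=1e-15)
        ]
        most_central[method] = min(tied)
    return {
        "disease": disease_curie,
        "taxa": sorted(taxa),
        "most_central": most_central,
        "tables": tables,
    }


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class PublicationSummary:
    publication_id: str
    n_nodes: int
    n_edges_total: int
    n_edges_unique: int
    bounds: dict[str, float]


def publication_summary(
    graph: KnowledgeGraph, registry: PredicateRegistry
) -> list[PublicationSummary]:
    """Per-publication node/edge/unique-edge counts with theoretical bounds.

    Bounds on the unique edge count given n incident nodes: n(n-1)/2 for a
    fully connected simple graph, n-1 for a connected graph lacking any
    cliques, and n/2 with no connectivity requirement.
    """
    by_pub: dict[str, list[Edge]] = {}
    for e in graph.edges:
        by_pub.setdefault(e.provenance.get("publication_id", ""), []).append(e)
    out = []
    for pub in sorted(by_pub):
        edges = by_pub[pub]
        nodes = {e.subject for e in edges} | {e.object for e in edges}
        n = len(nodes)
        sub = KnowledgeGraph(nodes={c: graph.nodes[c] for c in nodes}, edges=edges)
        out.append(
            PublicationSummary(
                publication_id=pub,
                n_nodes=n,
                n_edges_total=len(edges),
                n_edges_unique=unique_edge_count(sub, registry),
                bounds={
                    "max_unique": n * (n - 1) / 2,
                    "min_connected": n - 1,
                    "min_unconstrained": n / 2,
                },
            )
        )
    return out


@dataclass
class MetagraphSummary:
    class_counts: dict[str, int]
    arc_counts: dict[tuple[str, str, str], int]


def metagraph(graph: KnowledgeGraph, registry: PredicateRegistry) -> MetagraphSummary:
    """Class-level summary: node counts per Biolink class, edge counts per
    (subject class, predicate, object class) arc.

    Symmetric-predicate arcs are canonicalized by lexicographic class order
    so that the two storage directions of the same relationship coincide.
    Conservation holds by construction: class counts sum to the node count
    and arc counts sum to the edge count.
    """
    class_counts: dict[str, int] = {}
    for node in graph.nodes.values():
        class_counts[node.category] = class_counts.get(node.category, 0) + 1
    arc_counts: dict[tuple[str, str, str], int] = {}
    for e in graph.edges:
        s_cls = graph.nodes[e.subject].category
        o_cls = graph.nodes[e.object].category
        if registry.is_symmetric(e.predicate):
            s_cls, o_cls = sorted((s_cls, o_cls))
        key = (s_cls, e.predicate, o_cls)
        arc_counts[key] = arc_counts.get(key, 0) + 1
    return MetagraphSummary(class_counts=class_counts, arc_counts=arc_counts)
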