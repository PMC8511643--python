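"""Disease semantic similarity over per-disease ancestor DAGs.

Each disease D is represented by the DAG ``(T(D), E(D))`` of its ontology
term plus all ancestor terms.  A term ``d`` contributes to D's semantics
with a value that decays geometrically with distance from D:

    contribution(D)  = 1
    contribution(d)  = max over children d' of d (within the DAG) of
                       omega * contribution(d'),   d != D

with semantic contribution factor ``omega`` (default 0.5).  The semantic
value ``V(D)`` is the sum of contributions over ``T(D)``, and the
similarity of two diseases is the contribution mass of their shared
terms, normalised by the sum of semantic values:

    SD(di, dj) = sum_{t in T(di) & T(dj)} (c_i(t) + c_j(t)) / (V(di) + V(dj))

which is symmetric, 1 on the diagonal and bounded in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import OntologyInput, SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_OMEGA = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease's ancestor DAG: its term, all ancestors, and the
    child-to-parent edges induced among them."""

    disease: str
    term: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.term not in self.nodes:
            raise ValueError(f"{self.disease}: disease term must belong to its DAG")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"{self.disease}: ancestor graph contains a cycle")
        reachable = {self.term} | nx.descendants(g, self.term)
        if reachable != set(self.nodes):
            raise ValueError(
                f"{self.disease}: every DAG node must be an ancestor of the disease term"
            )


def dag_from_ontology(ontology: OntologyInput, disease: str) -> DiseaseDAG:
    """Extract the ancestor DAG of one disease from a flattened ontology.

    A disease whose term does not appear in the ontology at all gets a
    singleton DAG (it can then only match itself), with a warning.
    """
    if disease not in ontology.disease_terms:
        raise KeyError(f"no ontology term mapped for disease {disease!r}")
    term = ontology.disease_terms[disease]
    g = ontology.graph()
    if term not in g:
        logger.warning(
            "disease %r: term %r absent from ontology edges; using singleton DAG",
            disease, term,
        )
        return DiseaseDAG(disease, term, frozenset({term}), frozenset())
    nodes = {term} | nx.descendants(g, term)  # edges run child -> parent
    edges = {(c, p) for c, p in g.edges if c in nodes and p in nodes}
    return DiseaseDAG(disease, term, frozenset(nodes), frozenset(edges))


def contribution(dag: DiseaseDAG, omega: float = DEFAULT_OMEGA) -> dict[str, float]:
    """Per-term semantic contribution values within one disease DAG.

    "children of d" means children within the DAG's induced edge set:
    contributions are defined per-disease, not on the global ontology.
    """
    if not 0 < omega <= 1:
        raise ValueError(f"omega must lie in (0, 1], got {omega}")
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    contrib: dict[str, float] = {}
    # child -> parent edges: topological order yields children before parents
    for node in nx.topological_sort(g):
        if node == dag.term:
            contrib[node] = 1.0
        else:
            children = [c for c, _ in g.in_edges(node)]
            contrib[node] = max(omega * contrib[c] for c in children)
    return contrib


def semantic_value(dag: DiseaseDAG, omega: float = DEFAULT_OMEGA) -> float:
    """V(D): total contribution mass of the disease's DAG; always >= 1."""
    return float(sum(contribution(dag, omega).values()))


def semantic_similarity_matrix(
    dags: list[DiseaseDAG], omega: float = DEFAULT_OMEGA
) -> SimilarityMatrix:
    """Pairwise semantic similarity SD over a list of disease DAGs."""
    names = [d.disease for d in dags]
    contribs = [contribution(d, omega) for d in dags]
    values = [sum(c.values()) for c in contribs]
    k = len(dags)
    sd = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            shared = dags[i].nodes & dags[j].nodes
            if shared:
                num = sum(contribs[i][t] + contribs[j][t] for t in shared)
                sd[i, j] = sd[j, i] = num / (values[i] + values[j])
    return SimilarityMatrix(names, sd, kind="semantic")


def semantic_similarity_from_ontology(
    ontology: OntologyInput,
    diseases: list[str],
    omega: float = DEFAULT_OMEGA,
) -> SimilarityMatrix:
    """Build SD for the given diseases straight from an ontology input."""
    dags = [dag_from_ontology(ontology, d) for d in diseases]
    return semantic_similarity_matrix(dags, omega)
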