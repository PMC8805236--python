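"""MeSH and MeSH-concept similarity networks and their summary statistics.

Nodes are MeSH terms (kind ``mesh``) or concepts (kind ``concept``); the
graph is undirected with edge weights in (0, 1]. MeSH-MeSH edges carry the
AMM information-content similarity of the two terms; MeSH-concept edges
carry the concept's normalised TF-IDF in the document that links them, with
the maximum kept when several documents induce the same pair.

A MeSH term can never merge with an identically-named concept: node kinds
keep the two families distinct, so concept node ids are prefixed by their
CUI namespace and counts always satisfy |V_expanded| = |V| + L, where L is
the number of distinct concepts retained in the corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .annotation import ConceptProfile
from .corpus_io import Corpus, MeshVocabulary
from .mesh_ontology import SimilarityParams, TreeIndex, mesh_term_similarity

logger = logging.getLogger(__name__)

MESH = "mesh"
CONCEPT = "concept"

DEFAULT_MIN_SIM = 0.1


@dataclass(frozen=True)
class NetworkStats:
    """Node/edge counts, average degree 2E/|V|, mean local clustering."""

    n_nodes: int
    n_mesh_nodes: int
    n_concept_nodes: int
    n_edges: int
    average_degree: float
    clustering_coefficient: float | None


def build_mesh_network(
    corpus: Corpus,
    vocab: MeshVocabulary,
    index: TreeIndex,
    params: SimilarityParams = SimilarityParams(),
    min_sim: float = DEFAULT_MIN_SIM,
) -> nx.Graph:
    """All-pairs AMM similarity over the MeSH terms observed in the corpus.

    An edge joins two terms iff their similarity is >= ``min_sim`` (every
    exp-form similarity is > 0, so a positive cutoff is what keeps the graph
    from being complete).
    """
    if min_sim <= 0:
        raise ValueError("min_sim must be > 0 (all similarities are positive)")
    terms = sorted({t for doc in corpus for t in doc.mesh_terms if t in vocab})
    if len(terms) < 2:
        raise ValueError("need at least 2 observed MeSH terms")
    g = nx.Graph()
    for term in terms:
        g.add_node(term, kind=MESH)
    for t1, t2 in combinations(terms, 2):
        sim = mesh_term_similarity(t1, t2, vocab, index, params)
        if sim >= min_sim:
            g.add_edge(t1, t2, weight=sim)
    return g


def expand_with_concepts(
    g: nx.Graph,
    concept_profile: ConceptProfile,
    corpus: Corpus,
) -> nx.Graph:
    """Add each document's retained concepts as nodes linked to its MeSH terms.

    Concept nodes are global (one node per CUI). Each edge weight is the
    concept's normalised TF-IDF in the contributing document; duplicate
    (MeSH, CUI) pairs keep the maximum weight. Existing MeSH-MeSH edges are
    untouched. Zero-weight links are skipped with a warning.
    """
    expanded = g.copy()
    for doc in corpus:
        mesh_nodes = [t for t in doc.mesh_terms if t in g]
        for cui in sorted(concept_profile.cuis_of(doc.pmid)):
            weight = concept_profile.normalized_weight(doc.pmid, cui)
            if weight <= 0:
                logger.warning(
                    "concept %s in document %s has zero weight; edge skipped",
                    cui, doc.pmid,
                )
                continue
            if cui not in expanded:
                expanded.add_node(cui, kind=CONCEPT)
            for term in mesh_nodes:
                if expanded.has_edge(term, cui):
                    if weight > expanded[term][cui]["weight"]:
                        expanded[term][cui]["weight"] = weight
                else:
                    expanded.add_edge(term, cui, weight=weight)
    return expanded


def network_stats(g: nx.Graph, include_clustering: bool = True) -> NetworkStats:
    """Summary statistics; clustering is the unweighted mean local
    coefficient (degree<2 nodes count 0) and can be skipped on large graphs."""
    n = g.number_of_nodes()
    e = g.number_of_edges()
    kinds = nx.get_node_attributes(g, "kind")
    n_concept = sum(1 for k in kinds.values() if k == CONCEPT)
    n_mesh = n - n_concept
    if n == 0:
        return NetworkStats(0, 0, 0, 0, 0.0, 0.0 if include_clustering else None)
    clustering = nx.average_clustering(g) if include_clustering else None
    return NetworkStats(
        n_nodes=n,
        n_mesh_nodes=n_mesh,
        n_concept_nodes=n_concept,
        n_edges=e,
        average_degree=2.0 * e / n,
        clustering_coefficient=clustering,
    )


def prune(g: nx.Graph, threshold: float) -> nx.Graph:
    """Drop edges with weight < threshold; keep all nodes (idempotent)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    pruned = g.copy()
    to_drop = [
        (u, v) for u, v, w in pruned.edges(data="weight") if w < threshold
    ]
    pruned.remove_edges_from(to_drop)
    return pruned


def write_edgelist(g: nx.Graph, path) -> None:
    """Weighted edge-list TSV plus a commented node-kind preamble (so
    isolated nodes and kinds survive a round trip)."""
    with open(path, "w", encoding="utf-8") as handle:
        for node in sorted(g.nodes):
            handle.write(f"#node\t{node}\t{g.nodes[node].get('kind', MESH)}\n")
        for u, v, w in sorted(g.edges(data="weight")):
            handle.write(f"{u}\t{v}\t{w!r}\n")


def read_edgelist(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#node\t"):
                _, node, kind = line.split("\t")
                g.add_node(node, kind=kind)
            else:
                u, v, w = line.split("\t")
                g.add_edge(u, v, weight=float(w))
    return g
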