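"""End-to-end orchestration: inputs -> networks -> features -> similarity -> scores.

This is the library face of the command line: a :class:`RunConfig` collects
every tunable with the method's standard defaults (restart probability 0.6,
similarity-decay scale epsilon 3, convergence tolerance 1e-10, PMRA rates
lambda 0.022 / mu 0.013, five concepts per document), and
:func:`run_pipeline` executes the stages for one of the three methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import (
    ConceptProfile,
    StemProfile,
    build_concept_profiles,
    build_stem_profiles,
)
from .corpus_io import attach_topics
from .mesh_ontology import SimilarityParams, TreeIndex
from .network import DEFAULT_MIN_SIM, build_mesh_network, expand_with_concepts
from .rwr import RWRConfig, document_feature_vectors
from .similarity import (
    MCRWR,
    MRWR,
    PMRA,
    DocSimilarityMatrix,
    PMRAParams,
    pmra_similarity,
    rwr_doc_similarity,
)
from .synthetic import SyntheticBundle

logger = logging.getLogger(__name__)

METHODS = (MCRWR.lower(), MRWR.lower(), PMRA.lower())


@dataclass(frozen=True)
class RunConfig:
    method: str = "mcrwr"
    alpha: float = 0.6
    tol: float = 1e-10
    max_iter: int = 10_000
    norm: str = "column"
    epsilon: float = 3.0
    min_sim: float = DEFAULT_MIN_SIM
    pmra: PMRAParams = field(default_factory=PMRAParams)
    prune_threshold: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")

    @property
    def rwr_config(self) -> RWRConfig:
        return RWRConfig(alpha=self.alpha, tol=self.tol, max_iter=self.max_iter, norm=self.norm)

    @property
    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(epsilon=self.epsilon)


@dataclass
class PipelineResult:
    similarity: DocSimilarityMatrix
    graph: object | None = None
    features: object | None = None
    feature_pmids: list[str] | None = None
    feature_nodes: list[str] | None = None
    stem_profile: StemProfile | None = None
    concept_profile: ConceptProfile | None = None


def rwr_seed_sets(bundle: SyntheticBundle, with_concepts: bool,
                  concept_profile: ConceptProfile | None) -> dict[str, set[str]]:
    """Seed nodes per document: its MeSH terms, plus its retained concepts
    on the MeSH-concept graph."""
    seeds: dict[str, set[str]] = {}
    for doc in bundle.corpus:
        s = set(doc.mesh_terms)
        if with_concepts and concept_profile is not None:
            s |= concept_profile.cuis_of(doc.pmid)
        seeds[doc.pmid] = s
    return seeds


def run_pipeline(bundle: SyntheticBundle, config: RunConfig = RunConfig()) -> PipelineResult:
    """Compute the pairwise document similarity matrix for one method.

    For the walk-based methods the stages are: corpus frequency index over
    tree numbers, all-pairs MeSH similarity network, optional concept
    expansion, restart walks from each document's seeds, pairwise cosine.
    PMRA skips the network and scores shared stems directly.
    """
    attach_topics(bundle.corpus, bundle.gold)
    method = config.method
    if method == "pmra":
        profile = build_stem_profiles(bundle.corpus)
        sim = pmra_similarity(bundle.corpus, profile, config.pmra)
        logger.info("pmra: %d documents", len(sim.pmids))
        return PipelineResult(similarity=sim, stem_profile=profile)

    index = TreeIndex.from_corpus(bundle.corpus, bundle.vocabulary)
    graph = build_mesh_network(
        bundle.corpus, bundle.vocabulary, index,
        config.similarity_params, min_sim=config.min_sim,
    )
    logger.info("mesh network: %d nodes, %d edges",
                graph.number_of_nodes(), graph.number_of_edges())
    concept_profile = None
    if method == "mcrwr":
        concept_profile = build_concept_profiles(bundle.corpus, bundle.lexicon)
        graph = expand_with_concepts(graph, concept_profile, bundle.corpus)
        logger.info("mesh-concept network: %d nodes, %d edges",
                    graph.number_of_nodes(), graph.number_of_edges())
    seeds = rwr_seed_sets(bundle, method == "mcrwr", concept_profile)
    features, pmids, nodes = document_feature_vectors(graph, seeds, config.rwr_config)
    logger.info("%s: %d feature vectors over %d nodes", method, len(pmids), len(nodes))
    sim = rwr_doc_similarity(features, pmids, method=method.upper())
    return PipelineResult(
        similarity=sim,
        graph=graph,
        features=features,
        feature_pmids=pmids,
        feature_nodes=nodes,
        stem_profile=None,
        concept_profile=concept_profile,
    )
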