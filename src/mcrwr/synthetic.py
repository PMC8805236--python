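"""Seeded synthetic corpora with known topic structure.

The generator emulates the shape of a topic-annotated MEDLINE subset:

* a MeSH-like forest of dotted tree numbers, one vocabulary term per
  non-root node, a fraction of terms holding a second tree number in a
  different category (so the average-maximum-match aggregation is exercised);
* topics anchored to "home" subtrees; each document draws 3-5 major MeSH
  terms mostly from its topic's home subtree, with a configurable leakage
  rate to terms elsewhere;
* titles and abstracts built from concept surface strings (shared within a
  topic at a configurable rate) plus filler prose words, so dictionary
  annotation and stem profiles both find signal;
* a qrels-style gold standard assigning each document its topic, with a
  configurable fraction of documents belonging to two topics.

``topic_separation`` in [0, 1] controls how many distinct root categories
host the topic home subtrees: at 1 every topic lives in its own category
(maximal tree distance between homes), at 0 all topics share one category.
All randomness flows from a single integer seed through ``random.Random``
with integer-based decisions only, so bundles are identical across platforms.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from ._words import CONCEPT_WORDS, FILLER_WORDS
from .corpus_io import (
    ConceptLexicon,
    Corpus,
    Document,
    GoldStandard,
    MeshVocabulary,
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    branching: int = 3
    depth: int = 3
    n_topics: int = 5
    docs_per_topic: int = 20
    mesh_per_doc: tuple[int, int] = (3, 5)
    concepts_per_doc: int = 5
    topic_separation: float = 1.0
    concept_sharing_rate: float = 0.6
    leakage: float = 0.1
    cross_topic_fraction: float = 0.1
    multi_number_fraction: float = 0.1
    topic_concept_pool: int = 8
    filler_concepts: int = 30
    abstract_length: tuple[int, int] = (50, 150)

    def __post_init__(self) -> None:
        if self.branching < 2 or self.depth < 2:
            raise ValueError("branching and depth must both be >= 2")
        if self.n_topics < 1 or self.docs_per_topic < 1:
            raise ValueError("need at least one topic and one document per topic")
        if not 0 <= self.topic_separation <= 1:
            raise ValueError("topic_separation must be in [0, 1]")

    @property
    def n_roots(self) -> int:
        """Root categories in the forest: one per topic, so the vocabulary is
        independent of ``topic_separation`` (only home placement varies)."""
        return self.n_topics

    @property
    def n_home_roots(self) -> int:
        """Distinct root categories hosting topic home subtrees."""
        return max(1, math.ceil(self.n_topics * self.topic_separation))


@dataclass
class SyntheticBundle:
    """A corpus plus every sidecar artifact the pipeline needs, and the
    generating ground truth (topic -> home subtree code)."""

    corpus: Corpus
    gold: GoldStandard
    vocabulary: MeshVocabulary
    lexicon: ConceptLexicon
    topic_homes: dict[str, str] = field(default_factory=dict)


def _term_name(code: str) -> str:
    return f"Mesh {code}"


def generate_tree(config: SyntheticConfig) -> MeshVocabulary:
    """Complete b-ary dotted hierarchies under ``n_roots`` category segments.

    Root segments (``A01``, ``A02``, ...) are categories, not terms; one
    vocabulary term is created per node at depth 1..depth. A seeded fraction
    of terms receives a second tree number drawn from another category.
    """
    rng = random.Random(config.seed)
    codes_by_root: dict[str, list[str]] = {}
    for r in range(config.n_roots):
        root = f"A{r + 1:02d}"
        level = [root]
        all_codes: list[str] = []
        for _ in range(config.depth):
            level = [f"{code}.{i + 1}" for code in level for i in range(config.branching)]
            all_codes.extend(level)
        codes_by_root[root] = all_codes

    entries: dict[str, set[str]] = {}
    roots = sorted(codes_by_root)
    for root in roots:
        for code in codes_by_root[root]:
            entries[_term_name(code)] = {code}
    if len(roots) > 1 and config.multi_number_fraction > 0:
        terms = sorted(entries)
        n_multi = int(round(config.multi_number_fraction * len(terms)))
        for term in rng.sample(terms, n_multi):
            own_root = next(iter(entries[term])).split(".")[0]
            other_root = rng.choice([r for r in roots if r != own_root])
            entries[term].add(rng.choice(codes_by_root[other_root]))
    return MeshVocabulary(entries=entries)


def _make_lexicon(config: SyntheticConfig, rng: random.Random):
    """Concept lexicon: per-topic pools of 1-2 word phrases plus shared
    filler concepts; returns (lexicon, topic pools, filler CUIs)."""
    entries: dict[str, set[str]] = {}
    next_id = 1

    def new_cui(words: list[str]) -> str:
        nonlocal next_id
        cui = f"C{next_id:07d}"
        next_id += 1
        entries[cui] = {" ".join(words)}
        return cui

    topic_pools: dict[str, list[str]] = {}
    for t in range(config.n_topics):
        topic = str(100 + t)
        pool = []
        for _ in range(config.topic_concept_pool):
            n_words = rng.choice([1, 2])
            words = [rng.choice(CONCEPT_WORDS) for _ in range(n_words)]
            pool.append(new_cui(words))
        topic_pools[topic] = pool
    filler = [new_cui([rng.choice(CONCEPT_WORDS), rng.choice(FILLER_WORDS)])
              for _ in range(config.filler_concepts)]
    return ConceptLexicon(entries=entries), topic_pools, filler


def generate_corpus(
    config: SyntheticConfig, vocabulary: MeshVocabulary | None = None
) -> SyntheticBundle:
    """Generate the full bundle: corpus, gold standard, vocabulary, lexicon."""
    if vocabulary is None:
        vocabulary = generate_tree(config)
    rng = random.Random(config.seed + 1)

    # topic homes are depth-1 subtrees, rotated over the first n_home_roots
    # categories: full separation puts every home in its own category,
    # low separation packs homes as sibling subtrees of a shared category
    roots = sorted({next(iter(codes)).split(".")[0] for codes in vocabulary.entries.values()})
    home_roots = roots[: min(config.n_home_roots, len(roots))]
    topics = [str(100 + t) for t in range(config.n_topics)]
    topic_homes: dict[str, str] = {}
    for i, topic in enumerate(topics):
        root = home_roots[i % len(home_roots)]
        subtree_idx = (i // len(home_roots)) % config.branching + 1
        topic_homes[topic] = f"{root}.{subtree_idx}"

    terms_by_home: dict[str, list[str]] = {home: [] for home in topic_homes.values()}
    all_terms = sorted(vocabulary.entries)
    for term in all_terms:
        primary = min(vocabulary.entries[term])
        for home in terms_by_home:
            if primary == home or primary.startswith(home + "."):
                terms_by_home[home].append(term)

    lexicon, topic_pools, filler_cuis = _make_lexicon(config, rng)

    def surface(cui: str) -> str:
        return next(iter(lexicon.entries[cui]))

    documents: list[Document] = []
    relevance: dict[tuple[str, str], int] = {}
    pmid_counter = 1
    lo_m, hi_m = config.mesh_per_doc
    lo_a, hi_a = config.abstract_length
    for topic in topics:
        home_terms = terms_by_home[topic_homes[topic]]
        for _ in range(config.docs_per_topic):
            pmid = str(pmid_counter)
            pmid_counter += 1
            n_mesh = rng.randint(lo_m, hi_m)
            mesh_terms: list[str] = []
            while len(mesh_terms) < n_mesh:
                if rng.random() < config.leakage or not home_terms:
                    term = rng.choice(all_terms)
                else:
                    term = rng.choice(home_terms)
                if term not in mesh_terms:
                    mesh_terms.append(term)

            doc_cuis = []
            for _ in range(config.concepts_per_doc):
                if rng.random() < config.concept_sharing_rate:
                    doc_cuis.append(rng.choice(topic_pools[topic]))
                else:
                    doc_cuis.append(rng.choice(filler_cuis))
            title_words = [surface(doc_cuis[0])] + [
                rng.choice(FILLER_WORDS) for _ in range(rng.randint(3, 6))
            ]
            rng.shuffle(title_words)
            abstract_words: list[str] = []
            target_len = rng.randint(lo_a, hi_a)
            while len(abstract_words) < target_len:
                if abstract_words and rng.random() < 0.15:
                    abstract_words.append(surface(rng.choice(doc_cuis)))
                else:
                    abstract_words.append(rng.choice(FILLER_WORDS))
            documents.append(
                Document(
                    pmid=pmid,
                    title=" ".join(title_words),
                    abstract=" ".join(abstract_words),
                    mesh_terms=mesh_terms,
                )
            )
            relevance[(topic, pmid)] = rng.choice([1, 2])

    # a seeded fraction of documents also belongs to a second topic
    if config.n_topics > 1 and config.cross_topic_fraction > 0:
        pmids = [d.pmid for d in documents]
        n_cross = int(round(config.cross_topic_fraction * len(pmids)))
        own_topic = {
            pmid: topic for (topic, pmid) in relevance
        }
        for pmid in rng.sample(pmids, n_cross):
            other = rng.choice([t for t in topics if t != own_topic[pmid]])
            relevance[(other, pmid)] = rng.choice([1, 2])

    gold = GoldStandard(relevance=relevance)
    corpus = Corpus(documents=documents, provenance=f"synthetic seed={config.seed}")
    for doc in corpus:
        doc.topics = sorted(gold.topics_of(doc.pmid))
    return SyntheticBundle(
        corpus=corpus,
        gold=gold,
        vocabulary=vocabulary,
        lexicon=lexicon,
        topic_homes=topic_homes,
    )
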