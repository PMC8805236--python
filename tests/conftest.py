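import pytest

from mcrwr.corpus_io import Corpus, Document, MeshVocabulary
from mcrwr.mesh_ontology import TreeIndex
from mcrwr.synthetic import SyntheticConfig, generate_corpus


def make_vocab(entries: dict[str, set[str]]) -> MeshVocabulary:
    return MeshVocabulary(entries={t: set(c) for t, c in entries.items()})


def make_corpus(mesh_by_pmid: dict[str, list[str]]) -> Corpus:
    return Corpus(
        documents=[
            Document(pmid=pmid, title=f"doc {pmid}", mesh_terms=list(terms))
            for pmid, terms in mesh_by_pmid.items()
        ]
    )


@pytest.fixture
def toy_vocab():
    """Five terms over a tiny two-category forest."""
    return make_vocab(
        {
            "Alpha": {"A01"},
            "AlphaOne": {"A01.1"},
            "AlphaTwo": {"A01.2"},
            "AlphaDeep": {"A01.1.1"},
            "Beta": {"B02"},
        }
    )


@pytest.fixture
def toy_index(toy_vocab):
    """Each term observed once per document listing it."""
    corpus = make_corpus(
        {
            "1": ["Alpha", "AlphaOne"],
            "2": ["AlphaOne", "AlphaDeep"],
            "3": ["AlphaTwo", "Beta"],
            "4": ["Beta", "Alpha"],
        }
    )
    return TreeIndex.from_corpus(corpus, toy_vocab)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact topic-separated synthetic study (3 topics x 8 documents)."""
    return generate_corpus(
        SyntheticConfig(seed=7, n_topics=3, docs_per_topic=8, topic_separation=1.0)
    )
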