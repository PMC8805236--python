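"""Text preprocessing and the three term-document matrices.

Titles and abstracts are lower-cased, stripped of punctuation and digits,
and whitespace-tokenised. Two parallel representations are then built:

* **stems** (for the PMRA baseline): Porter-stemmed tokens with weighted
  frequency ``k`` = 2 x title occurrences + 1 x abstract occurrences, document
  length ``l`` = sum of k, and idf = ln(D / df);
* **concepts** (for the random-walk methods): greedy longest-match dictionary
  annotation against a CUI lexicon on the preprocessed token stream, TF-IDF
  weighted with the same title coefficient, then reduced to each document's
  top five concepts and min-max normalised to [0, 1] corpus-wide.

Articles in MEDLINE typically carry 3-5 major MeSH terms, so capping at five
concepts keeps the two node families balanced in the expanded network.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import porter
from .corpus_io import ConceptLexicon, Corpus, Document

logger = logging.getLogger(__name__)

TITLE_WEIGHT = 2  # word-frequency coefficient for title occurrences
TOP_CONCEPTS = 5

_NON_ALPHA = re.compile(r"[^a-z]+")


def preprocess_text(title: str, abstract: str) -> tuple[list[str], list[str]]:
    """Lower-case, drop punctuation/digits, split on whitespace.

    Digit stripping means e.g. "p53" tokenises as "p".
    """

    def tokenize(text: str) -> list[str]:
        return [t for t in _NON_ALPHA.sub(" ", text.lower()).split() if t]

    return tokenize(title), tokenize(abstract)


def stem_tokens(tokens: list[str]) -> list[str]:
    """Porter-stem each token."""
    return [porter.stem(t) for t in tokens]


@dataclass
class StemProfile:
    """Weighted stem frequencies and document lengths for the whole corpus.

    ``k[pmid][stem]`` is the weighted frequency; ``length[pmid]`` the weighted
    token count; ``idf[stem]`` = ln(D / df).
    """

    k: dict[str, dict[str, int]]
    length: dict[str, int]
    df: dict[str, int]
    idf: dict[str, float]
    n_documents: int

    def stems_of(self, pmid: str) -> set[str]:
        return set(self.k[pmid])


def build_stem_profiles(corpus: Corpus) -> StemProfile:
    """Stem titles and abstracts; count with title coefficient 2."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    k: dict[str, dict[str, int]] = {}
    length: dict[str, int] = {}
    df: dict[str, int] = {}
    for doc in corpus:
        title_tokens, abstract_tokens = preprocess_text(doc.title, doc.abstract)
        counts: dict[str, int] = {}
        for s in stem_tokens(title_tokens):
            counts[s] = counts.get(s, 0) + TITLE_WEIGHT
        for s in stem_tokens(abstract_tokens):
            counts[s] = counts.get(s, 0) + 1
        k[doc.pmid] = counts
        length[doc.pmid] = sum(counts.values())
        for s in counts:
            df[s] = df.get(s, 0) + 1
    n = len(corpus)
    idf = {s: math.log(n / d) for s, d in df.items()}
    return StemProfile(k=k, length=length, df=df, idf=idf, n_documents=n)


def _lexicon_token_patterns(lexicon: ConceptLexicon) -> list[tuple[tuple[str, ...], str]]:
    """(token tuple, CUI) pairs, longest patterns first; ties by CUI so a
    surface string claimed by two CUIs resolves deterministically."""
    patterns: list[tuple[tuple[str, ...], str]] = []
    for cui, strings in lexicon.entries.items():
        for surface in strings:
            title_toks, _ = preprocess_text(surface, "")
            if title_toks:
                patterns.append((tuple(title_toks), cui))
    patterns.sort(key=lambda p: (-len(p[0]), p[0], p[1]))
    return patterns


def _match_tokens(tokens: list[str], patterns) -> dict[str, int]:
    """Greedy left-to-right longest non-overlapping dictionary match."""
    by_start: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for pat, cui in patterns:
        by_start.setdefault(pat[0], []).append((pat, cui))
    counts: dict[str, int] = {}
    i = 0
    while i < len(tokens):
        matched = False
        for pat, cui in by_start.get(tokens[i], ()):
            if tuple(tokens[i : i + len(pat)]) == pat:
                counts[cui] = counts.get(cui, 0) + 1
                i += len(pat)
                matched = True
                break
        if not matched:
            i += 1
    return counts


def annotate_concepts(
    doc: Document, lexicon: ConceptLexicon
) -> list[tuple[str, int, int]]:
    """Dictionary concept annotation of one document.

    Returns ``(CUI, title matches, abstract matches)`` triples, matched
    greedily (longest surface string wins, matches do not overlap) on the
    preprocessed token streams.
    """
    patterns = _lexicon_token_patterns(lexicon)
    title_tokens, abstract_tokens = preprocess_text(doc.title, doc.abstract)
    title_counts = _match_tokens(title_tokens, patterns)
    abstract_counts = _match_tokens(abstract_tokens, patterns)
    cuis = sorted(set(title_counts) | set(abstract_counts))
    return [(c, title_counts.get(c, 0), abstract_counts.get(c, 0)) for c in cuis]


@dataclass
class ConceptProfile:
    """Per-document top concepts with raw and normalised TF-IDF.

    ``concepts[pmid]`` maps CUI -> (raw tfidf, normalised tfidf in [0, 1]);
    at most five CUIs per document.
    """

    concepts: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def cuis_of(self, pmid: str) -> set[str]:
        return set(self.concepts.get(pmid, {}))

    def normalized_weight(self, pmid: str, cui: str) -> float:
        return self.concepts[pmid][cui][1]

    @property
    def all_cuis(self) -> set[str]:
        return {c for per_doc in self.concepts.values() for c in per_doc}


def build_concept_profiles(corpus: Corpus, lexicon: ConceptLexicon) -> ConceptProfile:
    """Annotate every document, keep the top five concepts by TF-IDF, and
    min-max normalise the retained weights corpus-wide.

    TF uses the title coefficient 2; idf = ln(D / df) with df counted over
    documents containing the CUI anywhere. Rank ties at the cutoff break by
    higher TF, then lexicographically smaller CUI. If all retained TF-IDFs
    are equal, every normalised weight is 1.
    """
    patterns = _lexicon_token_patterns(lexicon)
    tf: dict[str, dict[str, int]] = {}
    df: dict[str, int] = {}
    for doc in corpus:
        title_tokens, abstract_tokens = preprocess_text(doc.title, doc.abstract)
        title_counts = _match_tokens(title_tokens, patterns)
        abstract_counts = _match_tokens(abstract_tokens, patterns)
        counts = {
            c: TITLE_WEIGHT * title_counts.get(c, 0) + abstract_counts.get(c, 0)
            for c in set(title_counts) | set(abstract_counts)
        }
        tf[doc.pmid] = counts
        for c in counts:
            df[c] = df.get(c, 0) + 1
    n = len(corpus)
    idf = {c: math.log(n / d) for c, d in df.items()}

    raw: dict[str, dict[str, float]] = {}
    for pmid, counts in tf.items():
        scored = sorted(
            ((c, counts[c] * idf[c]) for c in counts),
            key=lambda item: (-item[1], -counts[item[0]], item[0]),
        )
        raw[pmid] = dict(scored[:TOP_CONCEPTS])

    values = [w for per_doc in raw.values() for w in per_doc.values()]
    profile = ConceptProfile()
    if not values:
        profile.concepts = {pmid: {} for pmid in raw}
        return profile
    lo, hi = min(values), max(values)
    span = hi - lo
    for pmid, per_doc in raw.items():
        if span == 0:
            profile.concepts[pmid] = {c: (w, 1.0) for c, w in per_doc.items()}
        else:
            profile.concepts[pmid] = {
                c: (w, (w - lo) / span) for c, w in per_doc.items()
            }
    return profile


@dataclass
class TermDocumentMatrices:
    """Aligned document-by-term matrices (pandas, documents as the index).

    ``mesh`` is 0/1 over major MeSH terms; ``stems`` holds weighted stem
    frequencies; ``concepts`` holds normalised TF-IDF, at most five nonzeros
    per row.
    """

    mesh: pd.DataFrame
    stems: pd.DataFrame
    concepts: pd.DataFrame


def build_matrices(
    corpus: Corpus,
    stem_profile: StemProfile,
    concept_profile: ConceptProfile,
) -> TermDocumentMatrices:
    """Assemble the three matrices from precomputed profiles.

    Documents with no MeSH terms are dropped from the MeSH matrix (they
    cannot seed a random walk) with a warning; they stay in the other two.
    """
    pmids = corpus.pmids
    mesh_terms = sorted({t for doc in corpus for t in doc.mesh_terms})
    mesh_rows = [p for p in pmids if corpus.get(p).mesh_terms]
    for doc in corpus:
        if not doc.mesh_terms:
            logger.warning("document %s has no MeSH terms; excluded from mesh matrix", doc.pmid)
    mesh = pd.DataFrame(0, index=mesh_rows, columns=mesh_terms, dtype=np.int8)
    for pmid in mesh_rows:
        for term in corpus.get(pmid).mesh_terms:
            mesh.loc[pmid, term] = 1

    stems = sorted({s for counts in stem_profile.k.values() for s in counts})
    stem_matrix = pd.DataFrame(0, index=pmids, columns=stems, dtype=np.int64)
    for pmid in pmids:
        for s, count in stem_profile.k[pmid].items():
            stem_matrix.loc[pmid, s] = count

    cuis = sorted(concept_profile.all_cuis)
    concept_matrix = pd.DataFrame(0.0, index=pmids, columns=cuis)
    for pmid in pmids:
        for cui in concept_profile.cuis_of(pmid):
            concept_matrix.loc[pmid, cui] = concept_profile.normalized_weight(pmid, cui)

    return TermDocumentMatrices(mesh=mesh, stems=stem_matrix, concepts=concept_matrix)
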