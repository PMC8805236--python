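"""Pairwise document similarity: cosine over walk features, and PMRA.

The walk-based methods (MCRWR on the MeSH-concept graph, MRWR on the
MeSH-only graph) compare two documents by the cosine of their convergent
restart-walk distributions. The PMRA baseline scores a pair by the sum of
term-weight products over the stems co-occurring in both documents'
titles and abstracts, with the Poisson-model weight

    W_{t,d} = sqrt(idf_t) / (1 + (mu/lambda)^(k-1) * exp(-(mu - lambda) l))

where k is the weighted stem frequency, l the weighted document length,
and (lambda, mu) the eliteness rates of the two-Poisson model (defaults
0.022 and 0.013). Raw PMRA scores are min-max normalised to [0, 1] over
all off-diagonal pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .annotation import StemProfile
from .corpus_io import Corpus, Document

MCRWR = "MCRWR"
MRWR = "MRWR"
PMRA = "PMRA"


@dataclass(frozen=True)
class PMRAParams:
    """Two-Poisson eliteness rates: lambda for elite, mu for non-elite use."""

    lam: float = 0.022
    mu: float = 0.013

    def __post_init__(self) -> None:
        if not 0 < self.mu < self.lam < 1:
            raise ValueError("require 0 < mu < lambda < 1")


@dataclass
class DocSimilarityMatrix:
    """Symmetric pairwise similarity with a method tag.

    ``values[i, j]`` is the similarity of ``pmids[i]`` and ``pmids[j]``;
    entries in [0, 1], diagonal 1.
    """

    pmids: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        n = len(self.pmids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match pmid list")

    def get(self, p1: str, p2: str) -> float:
        i, j = self.pmids.index(p1), self.pmids.index(p2)
        return float(self.values[i, j])

    def pairs(self):
        """Yield (pmid1, pmid2, similarity) over unordered off-diagonal pairs."""
        for i in range(len(self.pmids)):
            for j in range(i + 1, len(self.pmids)):
                yield self.pmids[i], self.pmids[j], float(self.values[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(f"#method\t{self.method}\n")
            for p1, p2, sim in self.pairs():
                handle.write(f"{p1}\t{p2}\t{sim!r}\n")


def cosine_similarity(p1: np.ndarray, p2: np.ndarray) -> float:
    """Cosine of two non-negative feature vectors, in [0, 1]."""
    n1, n2 = np.linalg.norm(p1), np.linalg.norm(p2)
    if n1 == 0 or n2 == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(p1, p2) / (n1 * n2))


def rwr_doc_similarity(
    features: np.ndarray, pmids: list[str], method: str = MCRWR
) -> DocSimilarityMatrix:
    """All-pairs cosine over the rows of the feature matrix."""
    if len(pmids) < 2:
        raise ValueError("need at least 2 documents")
    norms = np.linalg.norm(features, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero feature vector")
    unit = features / norms
    values = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return DocSimilarityMatrix(pmids=list(pmids), values=values, method=method)


def pmra_term_weight(
    t: str,
    doc: Document,
    profiles: StemProfile,
    params: PMRAParams = PMRAParams(),
) -> float:
    """Poisson-model weight of stem ``t`` in ``doc`` (requires k >= 1)."""
    k = profiles.k[doc.pmid].get(t, 0)
    if k < 1:
        raise ValueError(f"stem {t!r} does not occur in document {doc.pmid}")
    length = profiles.length[doc.pmid]
    idf = profiles.idf[t]
    denom = 1.0 + (params.mu / params.lam) ** (k - 1) * math.exp(
        -(params.mu - params.lam) * length
    )
    return math.sqrt(idf) / denom


def pmra_raw_scores(
    corpus: Corpus,
    profiles: StemProfile,
    params: PMRAParams = PMRAParams(),
) -> tuple[np.ndarray, list[str]]:
    """Unnormalised pairwise PMRA scores (sum over shared stems of the
    two documents' term weights)."""
    pmids = corpus.pmids
    stems = sorted({s for counts in profiles.k.values() for s in counts})
    col = {s: j for j, s in enumerate(stems)}
    weights = np.zeros((len(pmids), len(stems)))
    for i, doc in enumerate(corpus):
        for s in profiles.k[doc.pmid]:
            weights[i, col[s]] = pmra_term_weight(s, doc, profiles, params)
    # product is nonzero only where both documents carry the stem, so the
    # Gram matrix is exactly the shared-stem sum
    return weights @ weights.T, pmids


def pmra_similarity(
    corpus: Corpus,
    profiles: StemProfile,
    params: PMRAParams = PMRAParams(),
) -> DocSimilarityMatrix:
    """PMRA pairwise similarity, min-max normalised over off-diagonal pairs.

    Diagonal entries are set to 1; if all off-diagonal raw scores are equal
    the normalised value is 1 everywhere.
    """
    raw, pmids = pmra_raw_scores(corpus, profiles, params)
    n = len(pmids)
    if n < 2:
        raise ValueError("need at least 2 documents")
    off_diag = raw[~np.eye(n, dtype=bool)]
    lo, hi = off_diag.min(), off_diag.max()
    if hi == lo:
        values = np.ones_like(raw)
    else:
        values = (raw - lo) / (hi - lo)
        values = np.clip(values, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return DocSimilarityMatrix(pmids=pmids, values=values, method=PMRA)


def build_doc_network(sim: DocSimilarityMatrix, threshold: float) -> nx.Graph:
    """Document similarity network: edges where similarity >= threshold
    (equality kept), weight = similarity; the diagonal is ignored."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    g.add_nodes_from(sim.pmids)
    for p1, p2, value in sim.pairs():
        if value >= threshold:
            g.add_edge(p1, p2, weight=value)
    return g
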