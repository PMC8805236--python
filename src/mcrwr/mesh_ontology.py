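"""MeSH tree-number hierarchy and information-content term similarity.

A tree number is a dotted code like ``C04.588.945.418.365``; ancestry is
segment-prefix containment, so the closest common ancestor (cca) of two
codes is their longest shared whole-segment prefix. Term similarity follows
the information-content family:

* ``I(v) = -log( sum_{vi in des(v)} count(vi) / N )`` — informativeness of a
  node from the corpus frequency mass of its subtree;
* ``Dist(v1, v2) = I(v1) + I(v2) - 2 I(cca(v1, v2))`` — a Jiang–Conrath
  style distance;
* ``Sim(v1, v2) = exp(-Dist / epsilon)`` — mapped to (0, 1];
* term-level similarity by average maximum match (AMM) over the two terms'
  tree-number sets, since a MeSH term may sit at several tree positions.

Codes whose first segments differ live in disjoint categories; their cca is
a virtual root with ``I = 0`` (the root of the MeSH forest carries all the
frequency mass, so it is uninformative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .corpus_io import Corpus, MeshVocabulary, validate_tree_number


class VirtualRoot:
    """Sentinel for the common ancestor of disjoint MeSH categories."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "VirtualRoot"


VIRTUAL_ROOT = VirtualRoot()


@dataclass(frozen=True)
class SimilarityParams:
    """epsilon scales distance -> similarity decay; log base for I(v)."""

    epsilon: float = 3.0
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.log_base <= 1:
            raise ValueError("log base must be > 1")


def segments(code: str) -> tuple[str, ...]:
    return tuple(code.split("."))


def is_prefix(ancestor: str, descendant: str) -> bool:
    """Whole-segment prefix relation (a node is its own ancestor)."""
    a, d = segments(ancestor), segments(descendant)
    return len(a) <= len(d) and d[: len(a)] == a


def closest_common_ancestor(v1: str, v2: str) -> str | VirtualRoot:
    """Longest shared whole-segment prefix; VirtualRoot if categories differ."""
    validate_tree_number(v1)
    validate_tree_number(v2)
    s1, s2 = segments(v1), segments(v2)
    common: list[str] = []
    for a, b in zip(s1, s2):
        if a != b:
            break
        common.append(a)
    if not common:
        return VIRTUAL_ROOT
    return ".".join(common)


@dataclass
class TreeIndex:
    """Corpus-frequency index over the tree numbers of a vocabulary.

    ``counts[v]`` is the number of times a document's major MeSH term carrying
    tree number ``v`` occurs in the corpus (a term with several tree numbers
    increments each of them). Vocabulary nodes unobserved in the corpus get a
    pseudo-count of 1 so every subtree carries positive mass; ``total`` is the
    sum of the adjusted counts.
    """

    nodes: set[str]
    counts: dict[str, int]
    total: int
    _mass_cache: dict[str, int] = field(default_factory=dict, repr=False)

    @classmethod
    def from_corpus(cls, corpus: Corpus, vocab: MeshVocabulary) -> "TreeIndex":
        raw: dict[str, int] = {code: 0 for codes in vocab.entries.values() for code in codes}
        for doc in corpus:
            for term in doc.mesh_terms:
                if term not in vocab:
                    continue
                for code in vocab.tree_numbers(term):
                    raw[code] += 1
        counts = {code: (c if c > 0 else 1) for code, c in raw.items()}
        return cls(nodes=set(counts), counts=counts, total=sum(counts.values()))

    def subtree_mass(self, v: str) -> int:
        """Total adjusted count over all indexed nodes in v's subtree
        (prefix scan; v need not itself be indexed)."""
        if v not in self._mass_cache:
            self._mass_cache[v] = sum(
                c for node, c in self.counts.items() if is_prefix(v, node)
            )
        return self._mass_cache[v]


def descendants(v: str, index: TreeIndex) -> set[str]:
    """All indexed nodes whose code has v as a dotted prefix, v included."""
    if v not in index.nodes:
        raise KeyError(f"tree number {v!r} not in index")
    return {node for node in index.nodes if is_prefix(v, node)}


def information_content(
    v: str | VirtualRoot,
    index: TreeIndex,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """I(v) = -log(subtree mass / N); the virtual root has I = 0."""
    if isinstance(v, VirtualRoot):
        return 0.0
    if index.total <= 0:
        raise ValueError("index has no frequency mass")
    mass = index.subtree_mass(v)
    if mass <= 0:
        raise ValueError(f"tree number {v!r} has zero subtree mass")
    return -math.log(mass / index.total) / math.log(params.log_base)


def tree_distance(
    v1: str,
    v2: str,
    index: TreeIndex,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """Dist(v1, v2) = I(v1) + I(v2) - 2 I(cca(v1, v2)); >= 0."""
    cca = closest_common_ancestor(v1, v2)
    dist = (
        information_content(v1, index, params)
        + information_content(v2, index, params)
        - 2.0 * information_content(cca, index, params)
    )
    return max(dist, 0.0)  # guard float round-off at Dist ~ 0


def tree_similarity(
    v1: str,
    v2: str,
    index: TreeIndex,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """Sim(v1, v2) = exp(-Dist / epsilon), in (0, 1]."""
    return math.exp(-tree_distance(v1, v2, index, params) / params.epsilon)


def mesh_term_similarity(
    m1: str,
    m2: str,
    vocab: MeshVocabulary,
    index: TreeIndex,
    params: SimilarityParams = SimilarityParams(),
) -> float:
    """Average maximum match over the two terms' tree-number sets.

    Sum over each tree number of M1 of its best similarity to M2's numbers,
    plus the symmetric sum, divided by |m| + |n|. Equals 1 iff the terms
    share identical best-match positions (in particular for M1 == M2).
    """
    m = vocab.tree_numbers(m1)
    n = vocab.tree_numbers(m2)
    forward = sum(max(tree_similarity(v1, v2, index, params) for v2 in n) for v1 in m)
    backward = sum(max(tree_similarity(v2, v1, index, params) for v1 in m) for v2 in n)
    return (forward + backward) / (len(m) + len(n))
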