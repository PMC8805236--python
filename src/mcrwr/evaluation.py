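"""Retrieval evaluation against a topic gold standard.

Document pairs are labelled relevant iff the two documents share at least
one topic; a similarity matrix is then scored by

* ROC/AUC over a sweep of similarity thresholds (TPR = TP/(TP+FN),
  FPR = FP/(FP+TN); trapezoid area, identical to the rank-based
  Mann-Whitney AUC);
* P5 — for every document of a topic, the precision of its top five
  ranked neighbours, averaged per topic and then macro-averaged over topics;
* precision TP/(TP+FP) at a grid of thresholds, per topic (pairs with at
  least one member in the topic) and macro-averaged;
* community detection on the pruned document network compared with the
  topic member sets (identical / subset / mixed verdicts).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

from .corpus_io import GoldStandard
from .similarity import DocSimilarityMatrix

DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ROCCurve:
    """(FPR, TPR) points over the threshold sweep and the trapezoid area."""

    points: list[tuple[float, float]]
    auc: float


@dataclass
class PrecisionReport:
    """Per-topic P5 and threshold precisions with corpus macro means.

    ``precision_by_topic[t][th]`` is None when no pair is predicted similar
    at that threshold (undefined, not zero).
    """

    p5_by_topic: dict[str, float]
    corpus_p5: float
    precision_by_topic: dict[str, dict[float, float | None]]
    corpus_precision: dict[float, float | None]


@dataclass
class ClusterComparison:
    communities: dict[int, set[str]]
    cross_table: dict[int, dict[str, int]]
    verdicts: dict[int, str] = field(default_factory=dict)


def label_pairs(
    sim: DocSimilarityMatrix, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Pooled unordered document pairs with relevance labels.

    Documents absent from the gold standard are excluded. Returns
    (similarities, labels, pairs) aligned arrays; label 1 iff the pair
    shares a topic.
    """
    topics = {p: gold.topics_of(p) for p in sim.pmids if p in gold.judged_pmids}
    sims: list[float] = []
    labels: list[int] = []
    pairs: list[tuple[str, str]] = []
    for p1, p2, value in sim.pairs():
        if p1 not in topics or p2 not in topics:
            continue
        sims.append(value)
        labels.append(1 if topics[p1] & topics[p2] else 0)
        pairs.append((p1, p2))
    return np.asarray(sims), np.asarray(labels), pairs


def confusion_at_threshold(
    sims: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Predicted-similar iff similarity >= threshold."""
    predicted = sims >= threshold
    actual = labels.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(predicted & actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
    )


def roc_auc(sims: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC by sweeping every distinct similarity value as a threshold.

    The sweep includes a sentinel above the maximum so the curve starts at
    (0, 0) and ends at (1, 1); the area is the trapezoid rule over the
    sorted points and matches the rank-based AUC exactly.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both relevant and irrelevant pairs for a ROC curve")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    thresholds = np.concatenate(([np.inf], np.unique(sims)[::-1]))
    points = []
    for th in thresholds:
        predicted = sims >= th
        tp = int(np.sum(predicted & (labels == 1)))
        fp = int(np.sum(predicted & (labels == 0)))
        points.append((fp / n_neg, tp / n_pos))
    points.sort()
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(points=points, auc=auc)


def p5(sim: DocSimilarityMatrix, gold: GoldStandard) -> tuple[dict[str, float], float]:
    """Precision-at-5 per topic and its macro average over topics.

    For each document of a topic, all other judged documents are ranked by
    similarity (descending, ties broken by pmid); P5 of the document is the
    fraction of its top five that share a topic with it — the denominator
    stays 5 even when fewer relevant candidates exist, so topics with under
    five documents cannot reach 0.5. The topic's P5 averages its documents'.
    """
    judged = [p for p in sim.pmids if p in gold.judged_pmids]
    topics_of = {p: gold.topics_of(p) for p in judged}
    index = {p: i for i, p in enumerate(sim.pmids)}
    p5_by_topic: dict[str, float] = {}
    for topic, members in sorted(gold.topic_members.items()):
        doc_scores = []
        for pmid in sorted(members):
            if pmid not in index:
                continue
            i = index[pmid]
            candidates = sorted(
                (p for p in judged if p != pmid),
                key=lambda p: (-sim.values[i, index[p]], p),
            )[:5]
            hits = sum(1 for p in candidates if topics_of[p] & topics_of[pmid])
            doc_scores.append(hits / 5.0)
        if doc_scores:
            p5_by_topic[topic] = float(np.mean(doc_scores))
    corpus_p5 = float(np.mean(list(p5_by_topic.values()))) if p5_by_topic else 0.0
    return p5_by_topic, corpus_p5


def precision_at_thresholds(
    sim: DocSimilarityMatrix,
    gold: GoldStandard,
    thresholds=DEFAULT_THRESHOLDS,
) -> PrecisionReport:
    """Per-topic precision over a threshold grid, macro-averaged.

    A topic's pair set is every labelled pair with at least one member in
    the topic. Precision is undefined (None) where nothing is predicted
    similar; undefined topics are left out of the corpus mean.
    """
    sims, labels, pairs = label_pairs(sim, gold)
    members = gold.topic_members
    precision_by_topic: dict[str, dict[float, float | None]] = {}
    for topic, topic_pmids in sorted(members.items()):
        mask = np.array(
            [(p1 in topic_pmids or p2 in topic_pmids) for p1, p2 in pairs], dtype=bool
        )
        per_threshold: dict[float, float | None] = {}
        for th in thresholds:
            c = confusion_at_threshold(sims[mask], labels[mask], th)
            per_threshold[th] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
        precision_by_topic[topic] = per_threshold
    corpus_precision: dict[float, float | None] = {}
    for th in thresholds:
        defined = [
            v[th] for v in precision_by_topic.values() if v[th] is not None
        ]
        corpus_precision[th] = float(np.mean(defined)) if defined else None
    p5_by_topic, corpus_p5 = p5(sim, gold)
    return PrecisionReport(
        p5_by_topic=p5_by_topic,
        corpus_p5=corpus_p5,
        precision_by_topic=precision_by_topic,
        corpus_precision=corpus_precision,
    )


def detect_communities(
    g: nx.Graph, method: str = "infomap", seed: int = 0
) -> dict[int, set[str]]:
    """Community detection on a weighted document network.

    ``infomap`` uses the map-equation optimiser from igraph; the
    ``label_propagation`` alternative is the cheap deterministic-under-seed
    fallback. Both treat edge weights as connection strength. Returns
    community id -> node set (ids ordered by decreasing size, then by
    smallest member for determinism).
    """
    nodes = sorted(g.nodes)
    if not nodes:
        return {}
    node_index = {n: i for i, n in enumerate(nodes)}
    edges = [(node_index[u], node_index[v]) for u, v in g.edges]
    weights = [g[u][v].get("weight", 1.0) for u, v in g.edges]
    graph = ig.Graph(n=len(nodes), edges=edges, directed=False)
    rng_state = random.getstate()
    random.seed(seed)  # igraph's python binding draws from the stdlib RNG
    try:
        if method == "infomap":
            clustering = graph.community_infomap(edge_weights=weights or None)
        elif method == "label_propagation":
            clustering = graph.community_label_propagation(weights=weights or None)
        else:
            raise ValueError(f"unknown community method {method!r}")
    finally:
        random.setstate(rng_state)
    groups = [set(nodes[i] for i in community) for community in clustering]
    groups.sort(key=lambda s: (-len(s), min(s)))
    return {cid + 1: members for cid, members in enumerate(groups)}


def compare_clusters_to_topics(
    communities: dict[int, set[str]], gold: GoldStandard
) -> ClusterComparison:
    """Verdict per community against the topic member sets.

    ``identical-to-topic`` when the community equals some topic's member set
    (restricted to clustered documents), ``subset-of-topic`` when strictly
    inside one, ``mixed`` otherwise.
    """
    clustered = set().union(*communities.values()) if communities else set()
    topic_sets = {
        t: members & clustered for t, members in gold.topic_members.items()
    }
    cross: dict[int, dict[str, int]] = {}
    verdicts: dict[int, str] = {}
    for cid, members in communities.items():
        cross[cid] = {
            t: len(members & tset) for t, tset in topic_sets.items() if members & tset
        }
        if any(members == tset for tset in topic_sets.values() if tset):
            verdicts[cid] = "identical-to-topic"
        elif any(members < tset for tset in topic_sets.values()):
            verdicts[cid] = "subset-of-topic"
        else:
            verdicts[cid] = "mixed"
    return ClusterComparison(communities=communities, cross_table=cross, verdicts=verdicts)
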