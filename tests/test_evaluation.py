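import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from mcrwr.corpus_io import GoldStandard
from mcrwr.evaluation import (
    compare_clusters_to_topics,
    confusion_at_threshold,
    detect_communities,
    label_pairs,
    p5,
    precision_at_thresholds,
    roc_auc,
)
from mcrwr.similarity import DocSimilarityMatrix


def gold_from(topic_members: dict[str, list[str]]) -> GoldStandard:
    return GoldStandard(
        relevance={
            (t, p): 1 for t, pmids in topic_members.items() for p in pmids
        }
    )


def sim_matrix(pmids, pair_sims: dict[tuple[str, str], float]) -> DocSimilarityMatrix:
    n = len(pmids)
    idx = {p: i for i, p in enumerate(pmids)}
    values = np.eye(n)
    for (p1, p2), s in pair_sims.items():
        values[idx[p1], idx[p2]] = values[idx[p2], idx[p1]] = s
    return DocSimilarityMatrix(pmids=list(pmids), values=values, method="MCRWR")


class TestLabelPairs:
    def test_same_topic_triplet(self):
        gold = gold_from({"t": ["a", "b", "c"]})
        sim = sim_matrix(["a", "b", "c"], {})
        _, labels, pairs = label_pairs(sim, gold)
        assert len(pairs) == 3 and labels.sum() == 3  # C(3,2) relevant pairs

    def test_disjoint_topics_all_irrelevant(self):
        gold = gold_from({"t1": ["a"], "t2": ["b"], "t3": ["c"]})
        _, labels, _ = label_pairs(sim_matrix(["a", "b", "c"], {}), gold)
        assert labels.sum() == 0

    def test_cross_topic_document_links_both(self):
        gold = gold_from({"t1": ["a", "x"], "t2": ["x", "b"]})
        sim = sim_matrix(["a", "x", "b"], {})
        _, labels, pairs = label_pairs(sim, gold)
        relevant = {frozenset(p) for p, l in zip(pairs, labels) if l}
        assert relevant == {frozenset(("a", "x")), frozenset(("x", "b"))}

    def test_unjudged_documents_excluded(self):
        gold = gold_from({"t": ["a", "b"]})
        _, _, pairs = label_pairs(sim_matrix(["a", "b", "z"], {}), gold)
        assert all("z" not in p for p in pairs)


class TestConfusion:
    SIMS = np.array([0.9, 0.7, 0.3, 0.1])
    LABELS = np.array([1, 0, 1, 0])

    def test_threshold_zero_everything_predicted_similar(self):
        c = confusion_at_threshold(self.SIMS, self.LABELS, 0.0)
        assert (c.tp + c.fp, c.fn, c.tn) == (4, 0, 0)

    def test_threshold_above_one_nothing_predicted(self):
        c = confusion_at_threshold(self.SIMS, self.LABELS, 1.01)
        assert (c.tp, c.fp) == (0, 0) and c.fn + c.tn == 4

    def test_hand_enumerated_counts(self):
        c = confusion_at_threshold(self.SIMS, self.LABELS, 0.5)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)
        assert c.total == 4


def rank_auc(sims, labels):
    """Mann-Whitney identity: concordant pairs / (pos * neg), ties half."""
    pos = [s for s, l in zip(sims, labels) if l]
    neg = [s for s, l in zip(sims, labels) if not l]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        sims = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(sims, labels).auc == pytest.approx(1.0)

    def test_chance_level_on_random_labels(self):
        rng = np.random.default_rng(42)
        sims = rng.uniform(size=5000)
        labels = rng.integers(0, 2, size=5000)
        assert roc_auc(sims, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_six_pair_toy_equals_rank_count(self):
        sims = np.array([0.9, 0.5, 0.5, 0.4, 0.3, 0.2])
        labels = np.array([1, 1, 0, 0, 1, 0])
        assert roc_auc(sims, labels).auc == pytest.approx(rank_auc(sims, labels))

    def test_sweep_equals_rank_auc_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            sims = np.round(rng.uniform(size=n), 2)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            curve = roc_auc(sims, labels)
            assert curve.auc == pytest.approx(rank_auc(sims, labels), abs=1e-9)
            assert curve.auc == pytest.approx(roc_auc_score(labels, sims), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.5, 0.4]), np.array([1, 1]))

    def test_curve_monotone(self):
        rng = np.random.default_rng(9)
        sims = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        pts = roc_auc(sims, labels).points
        xs, ys = zip(*pts)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))


class TestP5:
    def test_all_top_five_relevant(self):
        pmids = [f"d{i}" for i in range(7)]
        gold = gold_from({"t": pmids[:6], "u": [pmids[6]]})
        sims = {
            (p1, p2): 0.9 for p1, p2 in itertools.combinations(pmids[:6], 2)
        }
        sims.update({(p, "d6"): 0.1 for p in pmids[:6]})
        by_topic, _ = p5(sim_matrix(pmids, sims), gold)
        assert by_topic["t"] == 1.0

    def test_small_topic_capped_below_half(self):
        # 3-document topic: even perfect ranking yields 2 relevant of 5
        pmids = [f"d{i}" for i in range(8)]
        gold = gold_from({"t": pmids[:3], "u": pmids[3:]})
        sims = {}
        for p1, p2 in itertools.combinations(pmids, 2):
            same = (p1 in pmids[:3]) == (p2 in pmids[:3])
            sims[(p1, p2)] = 0.9 if same else 0.1
        by_topic, _ = p5(sim_matrix(pmids, sims), gold)
        assert by_topic["t"] == pytest.approx(2 / 5)

    def test_exhaustive_ranking_oracle_eight_docs(self):
        rng = np.random.default_rng(13)
        pmids = [f"d{i}" for i in range(8)]
        gold = gold_from({"t1": pmids[:4], "t2": pmids[4:]})
        sims = {
            pair: float(np.round(rng.uniform(), 3))
            for pair in itertools.combinations(pmids, 2)
        }
        sim = sim_matrix(pmids, sims)
        by_topic, corpus_p5 = p5(sim, gold)
        # brute force: rank candidates per document, ties by pmid
        topics = {p: gold.topics_of(p) for p in pmids}
        expected = {}
        for topic, members in gold.topic_members.items():
            scores = []
            for q in sorted(members):
                ranked = sorted(
                    (p for p in pmids if p != q),
                    key=lambda p: (-sim.get(q, p), p),
                )[:5]
                scores.append(sum(1 for p in ranked if topics[p] & topics[q]) / 5)
            expected[topic] = np.mean(scores)
        assert by_topic == pytest.approx(expected)
        assert corpus_p5 == pytest.approx(np.mean(list(expected.values())))

    def test_macro_average_ignores_topic_size(self):
        pmids = [f"d{i}" for i in range(9)]
        gold = gold_from({"big": pmids[:6], "small": pmids[6:]})
        sims = {}
        for p1, p2 in itertools.combinations(pmids, 2):
            same = (p1 in pmids[:6]) == (p2 in pmids[:6])
            sims[(p1, p2)] = 0.9 if same else 0.1
        by_topic, corpus_p5 = p5(sim_matrix(pmids, sims), gold)
        assert corpus_p5 == pytest.approx((by_topic["big"] + by_topic["small"]) / 2)


class TestPrecisionAtThresholds:
    def test_threshold_zero_is_base_rate(self):
        gold = gold_from({"t": ["a", "b"], "u": ["c", "d"]})
        sims = {("a", "b"): 0.9, ("c", "d"): 0.8, ("a", "c"): 0.2,
                ("a", "d"): 0.3, ("b", "c"): 0.1, ("b", "d"): 0.2}
        report = precision_at_thresholds(sim_matrix(["a", "b", "c", "d"], sims), gold)
        # per topic at threshold 0: 1 relevant of 5 pairs touching the topic
        assert report.precision_by_topic["t"][0.0] == pytest.approx(1 / 5)

    def test_precision_one_beyond_separating_gap(self):
        gold = gold_from({"t": ["a", "b"], "u": ["c", "d"]})
        sims = {("a", "b"): 0.9, ("c", "d"): 0.95, ("a", "c"): 0.2,
                ("a", "d"): 0.1, ("b", "c"): 0.15, ("b", "d"): 0.1}
        report = precision_at_thresholds(sim_matrix(["a", "b", "c", "d"], sims), gold)
        assert report.corpus_precision[0.5] == 1.0

    def test_undefined_precision_is_none_not_zero(self):
        gold = gold_from({"t": ["a", "b"]})
        sims = {("a", "b"): 0.3}
        report = precision_at_thresholds(sim_matrix(["a", "b"], sims), gold)
        assert report.precision_by_topic["t"][0.9] is None
        assert report.corpus_precision[0.9] is None

    def test_nondecreasing_under_stochastic_dominance(self, small_bundle):
        from mcrwr.pipeline import RunConfig, run_pipeline

        result = run_pipeline(small_bundle, RunConfig())
        report = precision_at_thresholds(result.similarity, small_bundle.gold)
        defined = [v for v in report.corpus_precision.values() if v is not None]
        assert all(a <= b + 1e-9 for a, b in zip(defined, defined[1:]))


class TestClusterComparison:
    def test_verdicts(self):
        gold = gold_from(
            {"t1": ["a", "b", "c"], "t2": ["d", "e"], "t3": ["f", "g"]}
        )
        communities = {
            1: {"a", "b", "c"},   # identical to t1
            2: {"d"},             # strict subset of t2
            3: {"e", "f", "g"},   # spans t2 and t3
        }
        comparison = compare_clusters_to_topics(communities, gold)
        assert comparison.verdicts == {
            1: "identical-to-topic",
            2: "subset-of-topic",
            3: "mixed",
        }
        assert comparison.cross_table[3] == {"t2": 1, "t3": 2}


class TestDetectCommunities:
    @pytest.fixture
    def two_cliques(self):
        g = nx.Graph()
        for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
            for u, v in itertools.combinations(block, 2):
                g.add_edge(u, v, weight=0.9)
        g.add_edge("a1", "b1", weight=0.05)
        return g

    @pytest.mark.parametrize("method", ["infomap", "label_propagation"])
    def test_recovers_planted_cliques(self, two_cliques, method):
        communities = detect_communities(two_cliques, method=method, seed=1)
        groups = {frozenset(m) for m in communities.values()}
        assert frozenset({"a1", "a2", "a3", "a4"}) in groups
        assert frozenset({"b1", "b2", "b3", "b4"}) in groups

    def test_deterministic_under_seed(self, two_cliques):
        a = detect_communities(two_cliques, seed=3)
        b = detect_communities(two_cliques, seed=3)
        assert a == b

    def test_partition_covers_nodes(self, two_cliques):
        communities = detect_communities(two_cliques, seed=0)
        all_nodes = set().union(*communities.values())
        assert all_nodes == set(two_cliques.nodes)
        assert sum(len(m) for m in communities.values()) == len(all_nodes)
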