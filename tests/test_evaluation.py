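"""Ranking metrics against brute-force oracles.

The AUROC oracle counts concordant positive/negative pairs (ties count
half); the AUPR oracle recomputes the average-precision step sum by hand.
Both are evaluated on random instances and compared to the implementation
at tight tolerance.
"""

import numpy as np
import pytest

from agrn.data_io import GoldStandard, RankedEdgeList, RegulatorSet
from agrn.evaluation import (
    LabeledRanking,
    MetricUndefinedError,
    aupr,
    auroc,
    evaluate_predictions,
    label_edges,
    pr_points,
    roc_points,
    topk_confusion,
)


def _ranking(labels, scores=None, extra_pos=0, extra_neg=0):
    labels = np.asarray(labels, dtype=int)
    if scores is None:
        scores = -np.arange(len(labels), dtype=float)  # strictly decreasing
    scores = np.asarray(scores, dtype=float)
    return LabeledRanking(
        scores=scores,
        labels=labels,
        n_positives=int(labels.sum()) + extra_pos,
        n_negatives=int((1 - labels).sum()) + extra_neg,
    )


def _auroc_oracle(ranking):
    """Concordant-pair fraction, ties counting one half."""
    scores = list(ranking.scores) + [-np.inf] * (
        ranking.unranked_positives + ranking.unranked_negatives
    )
    labels = list(ranking.labels) + [1] * ranking.unranked_positives + [0] * ranking.unranked_negatives
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def _aupr_oracle(ranking):
    """Hand step sum over tied groups, recall against all universe positives."""
    order = np.argsort(-ranking.scores, kind="stable")
    scores = ranking.scores[order]
    labels = ranking.labels[order]
    area, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += int(j - i - labels[i:j].sum())
        recall = tp / ranking.n_positives
        area += (recall - prev_recall) * (tp / (tp + fp))
        prev_recall = recall
        i = j
    return area


class TestLabelEdges:
    GENES = ("G1", "G2", "G3")

    def test_direct_lookup(self):
        pred = RankedEdgeList(edges=(("G1", "G2", 0.9),))
        out = label_edges(pred, GoldStandard(labeled_pairs={("G1", "G2"): 1}),
                          RegulatorSet(tf_ids=("G1",)), self.GENES)
        assert list(out.labels) == [1]
        assert out.n_positives == 1
        assert out.n_negatives == 1  # (G1,G3)

    def test_unpredicted_positive_counts_in_totals(self):
        pred = RankedEdgeList(edges=(("G1", "G3", 0.5),))
        out = label_edges(pred, GoldStandard(labeled_pairs={("G1", "G2"): 1}),
                          RegulatorSet(tf_ids=("G1",)), self.GENES)
        assert out.n_positives == 1 and out.unranked_positives == 1
        # max achievable recall < 1: terminal recall in PR stays at 0 here
        assert aupr(out) == 0.0

    def test_unknown_gene_rejected(self):
        pred = RankedEdgeList(edges=(("G9", "G2", 0.5),))
        with pytest.raises(ValueError, match="G9"):
            label_edges(pred, GoldStandard(), RegulatorSet(tf_ids=("G1",)), self.GENES)

    def test_explicit_and_implied_negatives_equivalent(self):
        pred = RankedEdgeList(edges=(("G1", "G2", 0.9), ("G1", "G3", 0.4)))
        gold_implied = GoldStandard(labeled_pairs={("G1", "G2"): 1})
        gold_explicit = GoldStandard(labeled_pairs={("G1", "G2"): 1, ("G1", "G3"): 0})
        tfs = RegulatorSet(tf_ids=("G1",))
        a = label_edges(pred, gold_implied, tfs, self.GENES)
        b = label_edges(pred, gold_explicit, tfs, self.GENES)
        assert list(a.labels) == list(b.labels)
        assert (a.n_positives, a.n_negatives) == (b.n_positives, b.n_negatives)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(_ranking([1, 1, 0, 0])) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc(_ranking([1, 0, 1, 0, 0], scores=[3.0] * 5)) == 0.5

    def test_alternating_labels(self):
        # concordant pairs: 3 of 4
        assert auroc(_ranking([1, 0, 1, 0])) == 0.75

    def test_undefined_without_both_classes(self):
        with pytest.raises(MetricUndefinedError):
            auroc(_ranking([1, 1]))

    def test_reversal_complements_auroc(self, rng):
        # negating distinct scores reverses the ranking and flips the area
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 1, 0
        scores = rng.standard_normal(30)
        order = np.argsort(-scores)
        fwd = _ranking(labels[order], scores=scores[order])
        rev = _ranking(labels[order][::-1], scores=-scores[order][::-1])
        assert auroc(fwd) == pytest.approx(1.0 - auroc(rev), abs=1e-12)


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr(_ranking([1, 1])) == 1.0

    def test_hand_computed_step_sum(self):
        # 0.5*1 + 0.5*(2/3) = 0.8333...
        assert aupr(_ranking([1, 0, 1, 0])) == pytest.approx(5.0 / 6.0)

    def test_single_wrong_prediction_scores_zero(self):
        assert aupr(_ranking([0], extra_pos=1)) == 0.0

    def test_undefined_without_positives(self):
        with pytest.raises(MetricUndefinedError):
            aupr(_ranking([0, 0]))


class TestMetricOracles:
    def _random_instance(self, rng):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() == 0:
            labels[0] = 1
        if labels.sum() == n:
            labels[-1] = 0
        if rng.random() < 0.5:
            scores = np.sort(rng.integers(0, 6, size=n))[::-1].astype(float)  # many ties
        else:
            scores = np.sort(rng.standard_normal(n))[::-1]
        return _ranking(labels, scores=scores,
                        extra_pos=int(rng.integers(0, 3)),
                        extra_neg=int(rng.integers(0, 4)))

    def test_auroc_equals_concordant_pair_fraction(self, rng):
        for _ in range(100):
            ranking = self._random_instance(rng)
            assert auroc(ranking) == pytest.approx(_auroc_oracle(ranking), abs=1e-10)

    def test_aupr_equals_hand_step_sum(self, rng):
        for _ in range(100):
            ranking = self._random_instance(rng)
            assert aupr(ranking) == pytest.approx(_aupr_oracle(ranking), abs=1e-10)

    def test_metrics_invariant_under_monotone_transform(self, rng):
        for transform in (lambda s: 3 * s + 2, np.tanh, lambda s: s**3):
            for _ in range(10):
                ranking = self._random_instance(rng)
                warped = LabeledRanking(
                    scores=transform(ranking.scores), labels=ranking.labels,
                    n_positives=ranking.n_positives, n_negatives=ranking.n_negatives,
                )
                assert auroc(warped) == pytest.approx(auroc(ranking), abs=1e-12)
                assert aupr(warped) == pytest.approx(aupr(ranking), abs=1e-12)


class TestCurvesAndTopK:
    def test_roc_curve_endpoints_and_range(self, rng):
        ranking = _ranking(rng.integers(0, 2, size=20), extra_pos=1, extra_neg=1)
        pts = roc_points(ranking)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert all(0 <= x <= 1 and 0 <= y <= 1 for x, y in pts)

    def test_pr_curve_starts_at_canonical_point(self):
        pts = pr_points(_ranking([1, 0, 1]))
        assert pts[0] == (0.0, 1.0)
        assert all(0 <= x <= 1 and 0 <= y <= 1 for x, y in pts)

    def test_topk_counts(self):
        ranking = _ranking([1, 0, 1])
        assert topk_confusion(ranking, 2) == (1, 1)
        assert topk_confusion(ranking, 10) == (2, 1)
        assert topk_confusion(_ranking([1, 1, 1]), 3) == (3, 0)


class TestEvaluatePredictions:
    def test_perfect_prediction_summary(self):
        genes = ("G1", "G2", "G3")
        gold = GoldStandard(labeled_pairs={("G1", "G2"): 1})
        pred = RankedEdgeList(edges=(("G1", "G2", 1.0), ("G1", "G3", 0.5)))
        result = evaluate_predictions(pred, gold, RegulatorSet(tf_ids=("G1",)),
                                      genes, top_k=1)
        assert result.auroc == 1.0
        assert result.aupr == 1.0
        assert result.topk == (1, 0)
        payload = result.as_dict()
        assert payload["top_k"]["true_positives"] == 1
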