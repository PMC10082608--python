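"""DREAM-protocol scoring of a ranked edge list against a gold standard.

The evaluation universe is every directed (TF, gene) pair with TF in the
regulator set and TF != gene. Pairs labeled 1 in the gold standard are
positives; everything else in the universe — explicitly labeled 0 or
simply absent — is a negative. Predicted edges are ranked by score; edges
of the universe missing from the prediction list rank strictly below all
predicted edges as one exchangeable group, so unretrieved positives
depress recall but contribute no precision-recall area.

AUROC uses the tied-group (midrank / Mann-Whitney) convention: tied
scores step jointly, equivalent to averaging over their orderings. AUPR
is the average-precision step sum sum_i (R_i - R_{i-1}) * P_i over tied
groups, with no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_io import GoldStandard, RankedEdgeList, RegulatorSet

__all__ = [
    "MetricUndefinedError",
    "LabeledRanking",
    "EvaluationResult",
    "label_edges",
    "auroc",
    "aupr",
    "roc_points",
    "pr_points",
    "topk_confusion",
    "evaluate_predictions",
]


class MetricUndefinedError(ValueError):
    """The requested metric has no value on this input (e.g. no positives)."""


@dataclass(frozen=True)
class LabeledRanking:
    """Predictions in rank order with 0/1 labels and universe totals.

    ``n_positives``/``n_negatives`` count over the full pair universe, so
    they include positives and negatives that were never predicted;
    ``unranked_positives``/``unranked_negatives`` are those remainders.
    """

    scores: np.ndarray
    labels: np.ndarray
    n_positives: int
    n_negatives: int

    @property
    def unranked_positives(self) -> int:
        return self.n_positives - int(self.labels.sum())

    @property
    def unranked_negatives(self) -> int:
        return self.n_negatives - int((1 - self.labels).sum())


def label_edges(
    predictions: RankedEdgeList,
    gold: GoldStandard,
    tfs: RegulatorSet,
    genes: tuple[str, ...] | list[str],
) -> LabeledRanking:
    """Label each predicted edge against the gold standard.

    Raises if a prediction names an identifier outside the (TF, gene)
    universe. Gold positives lying outside the universe (unknown TF or
    gene) are ignored rather than counted as unreachable.
    """
    genes = tuple(genes)
    gene_set = set(genes)
    tf_set = set(tfs.tf_ids)
    if not tf_set <= gene_set:
        raise ValueError("every transcription factor must appear in the gene list")
    positives = {
        (r, t) for (r, t) in gold.positives
        if r in tf_set and t in gene_set and r != t
    }
    n_universe = len(tf_set) * (len(gene_set) - 1)
    scores, labels = [], []
    for reg, tgt, score in predictions:
        if reg not in tf_set:
            raise ValueError(f"predicted regulator {reg!r} is not a known transcription factor")
        if tgt not in gene_set:
            raise ValueError(f"predicted target {tgt!r} is not a known gene")
        scores.append(score)
        labels.append(1 if (reg, tgt) in positives else 0)
    n_pos = len(positives)
    return LabeledRanking(
        scores=np.asarray(scores, dtype=float),
        labels=np.asarray(labels, dtype=int),
        n_positives=n_pos,
        n_negatives=n_universe - n_pos,
    )


def auroc(ranking: LabeledRanking) -> float:
    """Area under the ROC curve (Mann-Whitney form, midranks for ties)."""
    if ranking.n_positives == 0 or ranking.n_negatives == 0:
        raise MetricUndefinedError("AUROC requires at least one positive and one negative")
    # materialize the unranked remainder as one tied group below every
    # predicted score
    floor = (ranking.scores.min() - 1.0) if ranking.scores.size else 0.0
    scores = np.concatenate([
        ranking.scores,
        np.full(ranking.unranked_positives + ranking.unranked_negatives, floor),
    ])
    labels = np.concatenate([
        ranking.labels,
        np.ones(ranking.unranked_positives, dtype=int),
        np.zeros(ranking.unranked_negatives, dtype=int),
    ])
    ranks = rankdata(scores, method="average")
    pos_ranks = ranks[labels == 1].sum()
    n_pos, n_neg = ranking.n_positives, ranking.n_negatives
    return float((pos_ranks - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(ranking: LabeledRanking) -> float:
    """Average-precision step sum over tied score groups.

    Recall is measured against all positives in the universe, so positives
    never retrieved cap the terminal recall below 1 and add no area.
    """
    if ranking.n_positives == 0:
        raise MetricUndefinedError("AUPR requires at least one positive")
    area = 0.0
    tp = fp = 0
    recall_prev = 0.0
    for _, group_tp, group_fp in _score_groups(ranking):
        tp += group_tp
        fp += group_fp
        recall = tp / ranking.n_positives
        precision = tp / (tp + fp)
        area += (recall - recall_prev) * precision
        recall_prev = recall
    return float(area)


def _score_groups(ranking: LabeledRanking):
    """Yield (score, positives, negatives) per tied group, descending."""
    scores, labels = ranking.scores, ranking.labels
    i, n = 0, len(scores)
    while i < n:
        j = i
        while j < n and scores[j] == scores[i]:
            j += 1
        group = labels[i:j]
        yield float(scores[i]), int(group.sum()), int(j - i - group.sum())
        i = j


def roc_points(ranking: LabeledRanking) -> list[tuple[float, float]]:
    """ROC curve vertices (fpr, tpr), from (0, 0) to (1, 1)."""
    if ranking.n_positives == 0 or ranking.n_negatives == 0:
        raise MetricUndefinedError("ROC requires at least one positive and one negative")
    points = [(0.0, 0.0)]
    tp = fp = 0
    for _, gtp, gfp in _score_groups(ranking):
        tp += gtp
        fp += gfp
        points.append((fp / ranking.n_negatives, tp / ranking.n_positives))
    points.append((1.0, 1.0))
    if points[-1] == points[-2]:
        points.pop()
    return points


def pr_points(ranking: LabeledRanking) -> list[tuple[float, float]]:
    """PR curve vertices (recall, precision), starting at the canonical (0, 1)."""
    if ranking.n_positives == 0:
        raise MetricUndefinedError("PR requires at least one positive")
    points = [(0.0, 1.0)]
    tp = fp = 0
    for _, gtp, gfp in _score_groups(ranking):
        tp += gtp
        fp += gfp
        points.append((tp / ranking.n_positives, tp / (tp + fp)))
    return points


def topk_confusion(ranking: LabeledRanking, k: int) -> tuple[int, int]:
    """(true positives, false positives) among the first min(k, n) predictions."""
    if k < 1:
        raise ValueError("k must be at least 1")
    head = ranking.labels[:k]
    tp = int(head.sum())
    return tp, int(head.size - tp)


@dataclass(frozen=True)
class EvaluationResult:
    """Summary of a prediction list against a gold standard."""

    auroc: float
    aupr: float
    n_positives: int
    n_negatives: int
    roc_curve: list[tuple[float, float]]
    pr_curve: list[tuple[float, float]]
    topk: tuple[int, int] | None = None
    k: int | None = None

    def as_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "roc_curve": [list(p) for p in self.roc_curve],
            "pr_curve": [list(p) for p in self.pr_curve],
        }
        if self.topk is not None:
            out["top_k"] = {
                "k": self.k,
                "true_positives": self.topk[0],
                "false_positives": self.topk[1],
            }
        return out


def evaluate_predictions(
    predictions: RankedEdgeList,
    gold: GoldStandard,
    tfs: RegulatorSet,
    genes: tuple[str, ...] | list[str],
    top_k: int | None = None,
) -> EvaluationResult:
    """Label, score and summarize a ranked edge list in one call."""
    ranking = label_edges(predictions, gold, tfs, genes)
    return EvaluationResult(
        auroc=auroc(ranking),
        aupr=aupr(ranking),
        n_positives=ranking.n_positives,
        n_negatives=ranking.n_negatives,
        roc_curve=roc_points(ranking),
        pr_curve=pr_points(ranking),
        topk=topk_confusion(ranking, top_k) if top_k is not None else None,
        k=top_k,
    )
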