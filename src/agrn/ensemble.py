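"""Combine per-method importance matrices into a final ranked edge list.

The final score of a candidate edge is the weighted mean

    R = (w1 * phi_RF + w2 * phi_ET + w3 * C_SV) / (w1 + w2 + w3)

with default weights (1, 0.5, 0.1) — equivalently the 10:5:1 ratio, since
a weighted mean is invariant to rescaling all weights. Because Shapley
summaries and summed SVR coefficients live on incommensurate scales, each
method's matrix is min-max normalized to [0, 1] before combination (a
documented choice, toggleable by simply not calling the normalizer).
Final scores are z-scored over the candidate edge population and the
edges are ranked descending, truncated to the top 100 000 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import RankedEdgeList
from .importance import ImportanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleWeights",
    "ScoreBundle",
    "normalize_method_scores",
    "combine_weighted",
    "zscore_scores",
    "rank_and_truncate",
    "grid_search_weights",
]

DEFAULT_EDGE_LIMIT = 100_000


@dataclass(frozen=True)
class EnsembleWeights:
    """Nonnegative method weights; only their ratio matters."""

    w_rfr: float = 1.0
    w_etr: float = 0.5
    w_svr: float = 0.1

    def __post_init__(self) -> None:
        for w in (self.w_rfr, self.w_etr, self.w_svr):
            if w < 0:
                raise ValueError("ensemble weights must be nonnegative")
        if self.w_rfr + self.w_etr + self.w_svr <= 0:
            raise ValueError("at least one ensemble weight must be positive")


@dataclass(frozen=True)
class ScoreBundle:
    """The per-method importance matrices plus their ensemble weights.

    ``svr_scores`` may be None (two-method mode): the SVR term and its
    weight are then dropped from the weighted mean.
    """

    rfr_scores: ImportanceMatrix
    etr_scores: ImportanceMatrix
    svr_scores: ImportanceMatrix | None = None
    weights: EnsembleWeights = EnsembleWeights()

    def __post_init__(self) -> None:
        mats = [self.rfr_scores, self.etr_scores]
        if self.svr_scores is not None:
            mats.append(self.svr_scores)
        ref = mats[0]
        for m in mats[1:]:
            if (m.regulator_ids != ref.regulator_ids
                    or m.target_ids != ref.target_ids):
                raise ValueError(
                    "importance matrices in a bundle must share identical "
                    "regulator and target orderings"
                )


def normalize_method_scores(m: ImportanceMatrix) -> ImportanceMatrix:
    """Min-max rescale the whole matrix to [0, 1].

    A constant matrix carries no ranking information and maps to all
    zeros, with a warning.
    """
    scores = m.scores
    if not np.all(np.isfinite(scores)):
        raise ValueError("importance matrix must be finite before normalization")
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        logger.warning("constant importance matrix (%s): normalized to all zeros",
                       m.method_tag or "untagged")
        out = np.zeros_like(scores)
    else:
        out = (scores - lo) / (hi - lo)
    return ImportanceMatrix(
        regulator_ids=m.regulator_ids, target_ids=m.target_ids,
        scores=out, method_tag=m.method_tag,
    )


def combine_weighted(bundle: ScoreBundle) -> ImportanceMatrix:
    """Elementwise weighted mean of the bundle's matrices."""
    w = bundle.weights
    if bundle.svr_scores is None:
        total = w.w_rfr + w.w_etr
        if total <= 0:
            raise ValueError("two-method mode needs w_rfr + w_etr > 0")
        combined = (w.w_rfr * bundle.rfr_scores.scores
                    + w.w_etr * bundle.etr_scores.scores) / total
    else:
        total = w.w_rfr + w.w_etr + w.w_svr
        combined = (w.w_rfr * bundle.rfr_scores.scores
                    + w.w_etr * bundle.etr_scores.scores
                    + w.w_svr * bundle.svr_scores.scores) / total
    return ImportanceMatrix(
        regulator_ids=bundle.rfr_scores.regulator_ids,
        target_ids=bundle.rfr_scores.target_ids,
        scores=combined,
        method_tag="ensemble",
    )


def zscore_scores(m: ImportanceMatrix) -> ImportanceMatrix:
    """Standardize the candidate-edge scores: (R - mu) / sigma.

    The mean and the population (n-denominator) standard deviation are
    taken over all (regulator, target != regulator) entries; self-entries
    are excluded and left unscored (NaN). A zero spread leaves no ranking
    and raises.
    """
    mask = m.offdiagonal_mask()
    vals = m.scores[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 candidate-edge entries to z-score")
    mu = float(vals.mean())
    sigma = float(vals.std())  # population sd
    if sigma == 0.0:
        raise ValueError("zero variance across edge scores: no ranking possible")
    out = np.full_like(m.scores, np.nan)
    out[mask] = (m.scores[mask] - mu) / sigma
    return ImportanceMatrix(
        regulator_ids=m.regulator_ids, target_ids=m.target_ids,
        scores=out, method_tag=m.method_tag or "zscore",
    )


def rank_and_truncate(m: ImportanceMatrix, limit: int = DEFAULT_EDGE_LIMIT) -> RankedEdgeList:
    """Sort candidate edges by score descending and keep the top ``limit``.

    Ties are broken by (regulator, target) lexical order, so the ranking
    is stable across runs. Unscored (NaN) entries are skipped.
    """
    if limit < 1:
        raise ValueError("limit must be positive")
    entries = []
    for i, r in enumerate(m.regulator_ids):
        for j, t in enumerate(m.target_ids):
            if r == t:
                continue
            s = m.scores[i, j]
            if np.isnan(s):
                continue
            if not np.isfinite(s):
                raise ValueError(f"non-finite score at ({r}, {t})")
            entries.append((r, t, float(s)))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return RankedEdgeList(edges=tuple(entries[:limit]))


def grid_search_weights(
    bundle: ScoreBundle,
    score_fn,
    grid: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0),
) -> tuple[EnsembleWeights, float]:
    """Utility: grid-search ensemble weights against an arbitrary figure of merit.

    ``score_fn`` maps an :class:`ImportanceMatrix` (the combined scores) to
    a scalar to maximize — typically AUPR or AUROC against a gold standard.
    Weight triples are scanned over ``grid`` (scale-equivalent duplicates
    included; harmless since the combination is ratio-invariant), skipping
    all-zero triples; ties keep the first-scanned triple.
    """
    best: tuple[EnsembleWeights, float] | None = None
    for w1 in grid:
        for w2 in grid:
            for w3 in grid if bundle.svr_scores is not None else (0.0,):
                if w1 + w2 + w3 <= 0:
                    continue
                if bundle.svr_scores is None and w1 + w2 <= 0:
                    continue
                weights = EnsembleWeights(w_rfr=w1, w_etr=w2, w_svr=w3)
                trial = ScoreBundle(
                    rfr_scores=bundle.rfr_scores,
                    etr_scores=bundle.etr_scores,
                    svr_scores=bundle.svr_scores,
                    weights=weights,
                )
                value = float(score_fn(combine_weighted(trial)))
                if best is None or value > best[1]:
                    best = (weights, value)
    assert best is not None
    return best
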