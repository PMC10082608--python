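"""End-to-end inference: expression matrix in, ranked edge list out."""

from __future__ import annotations

from dataclasses import replace

from .data_io import ExpressionMatrix, RankedEdgeList, RegulatorSet
from .ensemble import (
    DEFAULT_EDGE_LIMIT,
    EnsembleWeights,
    ScoreBundle,
    combine_weighted,
    normalize_method_scores,
    rank_and_truncate,
    zscore_scores,
)
from .importance import SVRConfig, TreeRegressorConfig, score_all_targets

__all__ = ["infer_network"]


def infer_network(
    expr: ExpressionMatrix,
    tfs: RegulatorSet | None = None,
    methods: tuple[str, ...] = ("rfr", "etr", "svr"),
    weights: EnsembleWeights | None = None,
    limit: int = DEFAULT_EDGE_LIMIT,
    seed: int = 0,
    n_jobs: int = 1,
    normalize: bool = True,
    zscore: bool = True,
    tree_config: TreeRegressorConfig | None = None,
    svr_config: SVRConfig | None = None,
    return_bundle: bool = False,
):
    """Run the full inference pipeline.

    Scores every gene against the candidate regulators with each selected
    method, min-max normalizes each method's matrix, combines them by the
    weighted mean, z-scores the combined scores and returns the ranked,
    truncated edge list. With ``methods=("rfr", "etr")`` the SVR branch is
    skipped entirely (two-method mode). If ``tfs`` is None every gene is a
    candidate regulator.
    """
    methods = tuple(methods)
    if "rfr" not in methods or "etr" not in methods:
        raise ValueError("methods must include 'rfr' and 'etr'")
    extra = set(methods) - {"rfr", "etr", "svr"}
    if extra:
        raise ValueError(f"unknown methods: {sorted(extra)}")
    if tfs is None:
        tfs = RegulatorSet(tf_ids=expr.gene_ids)
    if weights is None:
        weights = EnsembleWeights()

    def tree_cfg(kind: str) -> TreeRegressorConfig:
        base = tree_config or TreeRegressorConfig()
        return replace(base, method=kind)

    rfr = score_all_targets(expr, tfs, "rfr", tree_cfg("random_forest"),
                            master_seed=seed, n_jobs=n_jobs)
    etr = score_all_targets(expr, tfs, "etr", tree_cfg("extra_trees"),
                            master_seed=seed, n_jobs=n_jobs)
    svr = None
    if "svr" in methods:
        svr = score_all_targets(expr, tfs, "svr", svr_config or SVRConfig(),
                                master_seed=seed, n_jobs=n_jobs)
    if normalize:
        rfr = normalize_method_scores(rfr)
        etr = normalize_method_scores(etr)
        if svr is not None:
            svr = normalize_method_scores(svr)
    bundle = ScoreBundle(rfr_scores=rfr, etr_scores=etr, svr_scores=svr, weights=weights)
    combined = combine_weighted(bundle)
    final = zscore_scores(combined) if zscore else combined
    edges: RankedEdgeList = rank_and_truncate(final, limit=limit)
    if return_bundle:
        return edges, bundle
    return edges
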