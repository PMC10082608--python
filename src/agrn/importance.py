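"""Per-target-gene regulator importance scores.

Network inference is decomposed into one regression problem per target
gene: predict the target's expression from the candidate transcription
factors (the target itself excluded — self-regulation is never scored).
Three scorers are provided:

* ``rfr`` — random-forest regression with per-sample Shapley-value
  attributions, summarized per candidate;
* ``etr`` — extremely-randomized-trees regression, likewise;
* ``svr`` — stability selection over linear support-vector regression:
  the (C, epsilon) pair is tuned once per target by Bayesian optimization
  of cross-validated MSE, then the model is refit on many random row
  subsamples and the absolute coefficients of the top-ranked candidates
  are accumulated.

:func:`score_all_targets` assembles the per-target vectors into a
regulator x target importance matrix. Per-target seeds are derived by
hashing (master seed, target name), so results do not depend on the
order or parallelism of target processing.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .data_io import ExpressionMatrix, RegulatorSet
from .optimize import minimize_smbo
from .shapley import interventional_tree_shap

logger = logging.getLogger(__name__)

__all__ = [
    "TargetProblem",
    "TreeRegressorConfig",
    "SVRConfig",
    "ImportanceMatrix",
    "build_target_problem",
    "derive_target_seed",
    "shap_tree_importance",
    "optimize_svr_hyperparams",
    "svr_subsample_importance",
    "score_all_targets",
]

_TREE_METHODS = {"random_forest", "extra_trees"}
_AGGREGATIONS = {"mean_abs", "mean", "max_abs"}


@dataclass(frozen=True)
class TargetProblem:
    """One regression subproblem: predict a target from candidate TFs."""

    target_id: str
    candidate_ids: tuple[str, ...]
    features: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        if self.target_id in self.candidate_ids:
            raise ValueError("target gene may not be its own candidate regulator")
        features = np.asarray(self.features, dtype=float)
        response = np.asarray(self.response, dtype=float)
        if features.ndim != 2 or features.shape[1] != len(self.candidate_ids):
            raise ValueError("feature columns must align with candidate_ids")
        if response.shape != (features.shape[0],):
            raise ValueError("response length must equal the sample count")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "response", response)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ids)


@dataclass(frozen=True)
class TreeRegressorConfig:
    """Configuration of a tree-ensemble scorer.

    The split criterion is pinned to mean squared error — the quantity the
    underlying CART learner minimizes at each node. ``shap_background``
    caps the number of training rows used as the marginalization
    background for the interventional Shapley values; ``aggregation``
    selects the per-candidate summary of the per-sample signed values
    (mean absolute value by default).
    """

    method: str = "random_forest"
    n_trees: int = 100
    seed: int = 0
    shap_background: int = 50
    aggregation: str = "mean_abs"

    def __post_init__(self) -> None:
        if self.method not in _TREE_METHODS:
            raise ValueError(f"method must be one of {sorted(_TREE_METHODS)}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.shap_background < 1:
            raise ValueError("shap_background must be positive")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {sorted(_AGGREGATIONS)}")

    @property
    def split_criterion(self) -> str:
        return "squared_error"


@dataclass(frozen=True)
class SVRConfig:
    """Configuration of the subsampled linear-SVR scorer.

    Defaults follow the stability-selection protocol: 200 subsample
    iterations, each drawing between 20% and 80% of the rows without
    replacement, scoring only the top 5 candidates per iteration. The
    (C, epsilon) pair is tuned per target over log-scale boxes
    [1e-2, 1e3] x [1e-3, 1] by 20 evaluations of 5-fold cross-validated
    MSE, with (C=1, epsilon=0.1) anchored into the initial design.

    ``max_iter`` caps the libsvm solver's iterations per fit: at large C
    with tiny epsilon the dual solver's convergence time grows without
    bound, and a capped fit's coefficients are indistinguishable for
    ranking purposes.
    """

    n_iterations: int = 200
    subsample_low: float = 0.20
    subsample_high: float = 0.80
    top_k: int = 5
    C_bounds: tuple[float, float] = (1e-2, 1e3)
    epsilon_bounds: tuple[float, float] = (1e-3, 1.0)
    n_opt_evals: int = 20
    cv_folds: int = 5
    seed: int = 0
    anchor: tuple[float, float] = (1.0, 0.1)
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_low < self.subsample_high <= 1.0):
            raise ValueError("need 0 < subsample_low < subsample_high <= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        for lo, hi in (self.C_bounds, self.epsilon_bounds):
            if not (0 < lo <= hi):
                raise ValueError("bounds must be positive with low <= high")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.n_opt_evals < 1:
            raise ValueError("n_opt_evals must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")


@dataclass(frozen=True)
class ImportanceMatrix:
    """Regulator x target score table produced by one scoring method.

    Self-entries (where a regulator is scored against itself as target)
    are held at zero by the producers; :func:`agrn.ensemble.zscore_scores`
    replaces them with NaN to mark them unscored.
    """

    regulator_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    scores: np.ndarray
    method_tag: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.regulator_ids), len(self.target_ids)):
            raise ValueError("scores shape must be (n_regulators, n_targets)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "regulator_ids", tuple(self.regulator_ids))
        object.__setattr__(self, "target_ids", tuple(self.target_ids))
        for i, r in enumerate(self.regulator_ids):
            for j, t in enumerate(self.target_ids):
                if r == t and not (scores[i, j] == 0.0 or np.isnan(scores[i, j])):
                    raise ValueError(f"self-entry ({r}, {t}) must be zero or unscored")

    def entry(self, regulator: str, target: str) -> float:
        return float(
            self.scores[self.regulator_ids.index(regulator), self.target_ids.index(target)]
        )

    def offdiagonal_mask(self) -> np.ndarray:
        """Boolean mask of candidate (regulator, target != regulator) cells."""
        mask = np.ones_like(self.scores, dtype=bool)
        for i, r in enumerate(self.regulator_ids):
            for j, t in enumerate(self.target_ids):
                if r == t:
                    mask[i, j] = False
        return mask


def build_target_problem(
    expr: ExpressionMatrix, tfs: RegulatorSet, target_id: str
) -> TargetProblem:
    """Assemble the regression problem for one target gene.

    Candidates are the transcription factors minus the target itself, in
    their original order; the response is the target's expression column.
    """
    if target_id not in expr.gene_ids:
        raise KeyError(f"target gene {target_id!r} not in expression matrix")
    missing = [tf for tf in tfs.tf_ids if tf not in expr.gene_ids]
    if missing:
        raise KeyError(f"transcription factors absent from expression matrix: {missing}")
    candidates = tuple(tf for tf in tfs.tf_ids if tf != target_id)
    if not candidates:
        raise ValueError(
            f"no candidate regulators remain for target {target_id!r} "
            "after excluding self-regulation"
        )
    cols = [expr.index_of(c) for c in candidates]
    return TargetProblem(
        target_id=target_id,
        candidate_ids=candidates,
        features=expr.values[:, cols],
        response=expr.column(target_id),
    )


def derive_target_seed(master_seed: int, target_id: str) -> int:
    """Stable per-target seed from (master seed, target name).

    Hash-based so that results are independent of the order in which
    targets are processed and of the worker that processes them.
    """
    digest = hashlib.blake2b(
        f"{int(master_seed)}:{target_id}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)


def _background_rows(features: np.ndarray, cap: int) -> np.ndarray:
    n = features.shape[0]
    if n <= cap:
        return features
    idx = np.unique(np.linspace(0, n - 1, cap).round().astype(int))
    return features[idx]


def shap_tree_importance(
    problem: TargetProblem,
    config: TreeRegressorConfig,
    return_per_sample: bool = False,
):
    """Tree-ensemble importance of each candidate via Shapley values.

    Fits the configured ensemble on (features, response), computes
    per-sample interventional Shapley values of every candidate, and
    summarizes them per candidate (default: mean absolute value). A
    constant response yields an all-zero vector — trees never split.
    """
    if problem.n_samples < 2:
        raise ValueError("at least 2 samples are required to fit a tree ensemble")
    if np.ptp(problem.response) == 0.0:
        logger.warning(
            "constant response for target %s: all importances set to 0",
            problem.target_id,
        )
        zeros = np.zeros(problem.n_candidates)
        if return_per_sample:
            return zeros, np.zeros_like(problem.features), 0.0
        return zeros
    cls = RandomForestRegressor if config.method == "random_forest" else ExtraTreesRegressor
    model = cls(
        n_estimators=config.n_trees,
        criterion=config.split_criterion,
        random_state=int(config.seed),
        n_jobs=1,
    )
    model.fit(problem.features, problem.response)
    background = _background_rows(problem.features, config.shap_background)
    phi, base = interventional_tree_shap(model, problem.features, background)
    if config.aggregation == "mean_abs":
        importance = np.abs(phi).mean(axis=0)
    elif config.aggregation == "mean":
        importance = phi.mean(axis=0)
    else:
        importance = np.abs(phi).max(axis=0)
    if return_per_sample:
        return importance, phi, base
    return importance


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd


def _fit_svr(features: np.ndarray, response: np.ndarray, C: float, epsilon: float,
             max_iter: int) -> SVR:
    model = SVR(kernel="linear", C=C, epsilon=epsilon, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(features, response)
    return model


def _cv_mse(features: np.ndarray, response: np.ndarray, C: float, epsilon: float,
            folds: int, max_iter: int) -> float:
    kf = KFold(n_splits=folds, shuffle=False)
    errors = []
    for train, test in kf.split(features):
        model = _fit_svr(features[train], response[train], C, epsilon, max_iter)
        pred = model.predict(features[test])
        errors.append(float(np.mean((pred - response[test]) ** 2)))
    return float(np.mean(errors))


def optimize_svr_hyperparams(
    problem: TargetProblem,
    config: SVRConfig,
    return_details: bool = False,
):
    """Tune (C, epsilon) by Bayesian optimization of cross-validated MSE.

    The search runs in log10 space over the configured boxes. The anchor
    point is always part of the initial design, so the returned pair's
    CV-MSE can never exceed the anchor's on the same folds. A degenerate
    (constant) response returns the anchor with a warning.
    """
    X = _standardize(problem.features)
    y = problem.response
    anchor = (float(np.clip(config.anchor[0], *config.C_bounds)),
              float(np.clip(config.anchor[1], *config.epsilon_bounds)))
    if np.ptp(y) == 0.0:
        logger.warning(
            "constant response for target %s: returning anchor hyperparameters",
            problem.target_id,
        )
        if return_details:
            return anchor, None
        return anchor
    y = _standardize(y)
    folds = min(config.cv_folds, problem.n_samples)
    if folds < 2:
        raise ValueError("at least 2 samples are required for cross-validation")

    def objective(point: np.ndarray) -> float:
        C = 10.0 ** point[0]
        epsilon = 10.0 ** point[1]
        return _cv_mse(X, y, C, epsilon, folds, config.max_iter)

    bounds = [
        (math.log10(config.C_bounds[0]), math.log10(config.C_bounds[1])),
        (math.log10(config.epsilon_bounds[0]), math.log10(config.epsilon_bounds[1])),
    ]
    rng = np.random.default_rng([int(config.seed), 2])
    result = minimize_smbo(
        objective,
        bounds,
        n_calls=config.n_opt_evals,
        rng=rng,
        anchor=np.array([math.log10(anchor[0]), math.log10(anchor[1])]),
    )
    tuned = (float(10.0 ** result.x[0]), float(10.0 ** result.x[1]))
    if return_details:
        return tuned, result
    return tuned


def svr_subsample_importance(
    problem: TargetProblem,
    config: SVRConfig,
    hyperparams: tuple[float, float] | None = None,
    return_details: bool = False,
):
    """Stability-selection importance from subsampled linear SVR fits.

    Hyperparameters are fixed once per target (see
    :func:`optimize_svr_hyperparams`). Each iteration draws ``r`` rows
    without replacement, with ``r`` uniform on
    ``[ceil(subsample_low * S), floor(subsample_high * S)]``, standardizes
    features and response on the subsample, fits the SVR, and adds the
    absolute coefficients of the ``top_k`` highest-|coefficient|
    candidates (ties broken by candidate identifier) to a running total.
    """
    S = problem.n_samples
    if S < 5:
        raise ValueError("at least 5 samples are required for subsampled SVR scoring")
    r_lo = math.ceil(config.subsample_low * S)
    r_hi = math.floor(config.subsample_high * S)
    r_lo = max(r_lo, 2)
    if r_hi < r_lo:
        raise ValueError(
            f"subsample bounds degenerate at S={S}: need at least "
            f"{math.ceil(2 / config.subsample_high)} samples"
        )
    if hyperparams is None:
        hyperparams = optimize_svr_hyperparams(problem, config)
    C, epsilon = hyperparams
    rng = np.random.default_rng([int(config.seed), 3])
    totals = np.zeros(problem.n_candidates)
    order_key = np.argsort(np.array(problem.candidate_ids))
    rank_of_id = np.empty(problem.n_candidates, dtype=int)
    rank_of_id[order_key] = np.arange(problem.n_candidates)
    details: list[dict] = []
    constant_response = np.ptp(problem.response) == 0.0
    for _ in range(config.n_iterations):
        r = int(rng.integers(r_lo, r_hi + 1))
        rows = rng.choice(S, size=r, replace=False)
        if constant_response:
            # nothing to learn; the iteration still consumes its draws
            if return_details:
                details.append({"r": r, "scored": ()})
            continue
        X = _standardize(problem.features[rows])
        y = problem.response[rows]
        if np.ptp(y) == 0.0:
            if return_details:
                details.append({"r": r, "scored": ()})
            continue
        y = _standardize(y)
        model = _fit_svr(X, y, C, epsilon, config.max_iter)
        coefs = np.abs(np.asarray(model.coef_).ravel())
        # stable top-k: by descending |coefficient|, ties by candidate id
        order = np.lexsort((rank_of_id, -coefs))
        top = order[: config.top_k]
        totals[top] += coefs[top]
        if return_details:
            details.append(
                {"r": r, "scored": tuple(problem.candidate_ids[i] for i in top)}
            )
    if return_details:
        return totals, {"hyperparams": (C, epsilon), "iterations": details}
    return totals


def _score_one_target(expr, tfs, target_id, method, config, master_seed):
    try:
        problem = build_target_problem(expr, tfs, target_id)
        seed = derive_target_seed(master_seed, target_id)
        cfg = replace(config, seed=seed)
        if method in ("rfr", "etr"):
            vector = shap_tree_importance(problem, cfg)
        else:
            vector = svr_subsample_importance(problem, cfg)
    except Exception as exc:
        raise RuntimeError(f"scoring target {target_id!r} failed: {exc}") from exc
    return target_id, problem.candidate_ids, vector


def score_all_targets(
    expr: ExpressionMatrix,
    tfs: RegulatorSet,
    method: str,
    config: TreeRegressorConfig | SVRConfig | None = None,
    master_seed: int = 0,
    n_jobs: int = 1,
) -> ImportanceMatrix:
    """Score every gene as a target and assemble the importance matrix.

    ``method`` is one of ``rfr``, ``etr`` (Shapley values on a random
    forest / extra-trees ensemble) or ``svr`` (subsampled linear-SVR
    coefficients). Rows are the supplied transcription factors, columns
    all genes; self-entries are zero. Targets are processed independently
    with name-derived seeds, so any ``n_jobs`` yields the same matrix.
    """
    if method not in ("rfr", "etr", "svr"):
        raise ValueError("method must be one of 'rfr', 'etr', 'svr'")
    if config is None:
        if method == "rfr":
            config = TreeRegressorConfig(method="random_forest")
        elif method == "etr":
            config = TreeRegressorConfig(method="extra_trees")
        else:
            config = SVRConfig()
    if method in ("rfr", "etr"):
        expected = "random_forest" if method == "rfr" else "extra_trees"
        if not isinstance(config, TreeRegressorConfig) or config.method != expected:
            raise ValueError(f"method {method!r} requires a TreeRegressorConfig({expected})")
    elif not isinstance(config, SVRConfig):
        raise ValueError("method 'svr' requires an SVRConfig")

    targets = expr.gene_ids
    results = Parallel(n_jobs=n_jobs)(
        delayed(_score_one_target)(expr, tfs, t, method, config, master_seed)
        for t in targets
    )

    reg_index = {tf: i for i, tf in enumerate(tfs.tf_ids)}
    scores = np.zeros((len(tfs.tf_ids), len(targets)))
    for j, (target_id, candidate_ids, vector) in enumerate(results):
        if not np.all(np.isfinite(vector)) or np.any(np.asarray(vector) < 0):
            raise RuntimeError(
                f"non-finite or negative importance for target {target_id!r}"
            )
        for cid, value in zip(candidate_ids, vector):
            scores[reg_index[cid], j] = value
    return ImportanceMatrix(
        regulator_ids=tfs.tf_ids,
        target_ids=targets,
        scores=scores,
        method_tag=method,
    )
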