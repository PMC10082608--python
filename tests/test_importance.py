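import math
from dataclasses import replace

import numpy as np
import pytest

from agrn.data_io import ExpressionMatrix, RegulatorSet
from agrn.importance import (
    SVRConfig,
    TreeRegressorConfig,
    build_target_problem,
    derive_target_seed,
    optimize_svr_hyperparams,
    score_all_targets,
    shap_tree_importance,
    svr_subsample_importance,
)
from agrn.importance import TargetProblem, _cv_mse, _standardize


def _problem(rng, n=100, p=3, signal_col=0, noise=0.0):
    X = rng.standard_normal((n, p))
    y = X[:, signal_col].copy()
    if noise:
        y = y + noise * rng.standard_normal(n)
    return TargetProblem(
        target_id="T",
        candidate_ids=tuple(f"C{i+1}" for i in range(p)),
        features=X,
        response=y,
    )


class TestBuildTargetProblem:
    def test_target_excluded_from_candidates(self, tiny_expression):
        tfs = RegulatorSet(tf_ids=("G1", "G2"))
        prob = build_target_problem(tiny_expression, tfs, "G1")
        assert prob.candidate_ids == ("G2",)
        np.testing.assert_array_equal(prob.response, tiny_expression.column("G1"))

    def test_non_tf_target_keeps_all_tfs(self, tiny_expression):
        tfs = RegulatorSet(tf_ids=("G1", "G2"))
        prob = build_target_problem(tiny_expression, tfs, "G3")
        assert prob.candidate_ids == ("G1", "G2")

    def test_sole_tf_as_target_is_an_error(self, tiny_expression):
        tfs = RegulatorSet(tf_ids=("G1",))
        with pytest.raises(ValueError, match="no candidate regulators"):
            build_target_problem(tiny_expression, tfs, "G1")

    def test_unknown_target_is_an_error(self, tiny_expression):
        with pytest.raises(KeyError, match="G9"):
            build_target_problem(tiny_expression, RegulatorSet(tf_ids=("G1",)), "G9")


class TestShapTreeImportance:
    def test_driving_candidate_dominates(self, rng):
        prob = _problem(rng, signal_col=0)
        imp = shap_tree_importance(prob, TreeRegressorConfig(seed=1))
        assert imp[0] > imp[1] and imp[0] > imp[2]
        # sanity: agrees with the correlation ranking on this clean problem
        corr = [abs(np.corrcoef(prob.features[:, j], prob.response)[0, 1]) for j in range(3)]
        assert int(np.argmax(imp)) == int(np.argmax(corr))

    def test_constant_response_scores_zero_with_warning(self, rng, caplog):
        prob = TargetProblem("T", ("C1", "C2"), rng.standard_normal((20, 2)), np.ones(20))
        with caplog.at_level("WARNING"):
            imp = shap_tree_importance(prob, TreeRegressorConfig(seed=0))
        np.testing.assert_array_equal(imp, 0.0)
        assert any("constant response" in r.message for r in caplog.records)

    def test_requires_two_samples(self, rng):
        prob = TargetProblem("T", ("C1",), rng.standard_normal((1, 1)), np.array([1.0]))
        with pytest.raises(ValueError, match="2 samples"):
            shap_tree_importance(prob, TreeRegressorConfig())

    def test_deterministic_given_seed(self, rng):
        prob = _problem(rng, noise=0.3)
        cfg = TreeRegressorConfig(seed=77)
        np.testing.assert_array_equal(
            shap_tree_importance(prob, cfg), shap_tree_importance(prob, cfg)
        )

    def test_nonnegative_and_finite(self, rng):
        prob = _problem(rng, noise=1.0)
        for method in ("random_forest", "extra_trees"):
            imp = shap_tree_importance(prob, TreeRegressorConfig(method=method, seed=3))
            assert np.all(np.isfinite(imp)) and np.all(imp >= 0)

    def test_column_permutation_equivariance(self, rng):
        # the delegated CART learner breaks split ties by feature visit
        # order, so tree importances are only statistically equivariant
        # under column permutation: same winner, close values
        prob = _problem(rng, p=4, signal_col=1, noise=0.2)
        perm = [2, 0, 3, 1]
        permuted = TargetProblem(
            "T",
            tuple(prob.candidate_ids[i] for i in perm),
            prob.features[:, perm],
            prob.response,
        )
        cfg = TreeRegressorConfig(seed=5)
        imp = shap_tree_importance(prob, cfg)
        imp_perm = shap_tree_importance(permuted, cfg)
        assert prob.candidate_ids[int(np.argmax(imp))] == \
            permuted.candidate_ids[int(np.argmax(imp_perm))]
        np.testing.assert_allclose(imp_perm, imp[perm], rtol=0.3, atol=1e-3)


class TestOptimizeSvr:
    def test_collapsed_bounds_return_that_point(self, rng):
        prob = _problem(rng, noise=0.2)
        cfg = SVRConfig(C_bounds=(2.0, 2.0), epsilon_bounds=(0.05, 0.05), seed=1)
        C, eps = optimize_svr_hyperparams(prob, cfg)
        assert C == pytest.approx(2.0) and eps == pytest.approx(0.05)

    def test_deterministic_given_seed(self, rng):
        prob = _problem(rng, noise=0.2)
        cfg = SVRConfig(seed=11, n_opt_evals=8)
        assert optimize_svr_hyperparams(prob, cfg) == optimize_svr_hyperparams(prob, cfg)

    def test_never_worse_than_anchor(self, rng):
        # recompute both objectives on identical folds and compare
        prob = _problem(rng, noise=0.5)
        cfg = SVRConfig(seed=3, n_opt_evals=10)
        (C, eps) = optimize_svr_hyperparams(prob, cfg)
        X = _standardize(prob.features)
        y = _standardize(prob.response)
        tuned = _cv_mse(X, y, C, eps, cfg.cv_folds, cfg.max_iter)
        anchor = _cv_mse(X, y, *cfg.anchor, cfg.cv_folds, cfg.max_iter)
        assert tuned <= anchor + 1e-12

    def test_constant_response_returns_anchor(self, rng, caplog):
        prob = TargetProblem("T", ("C1", "C2"), rng.standard_normal((30, 2)), np.zeros(30))
        with caplog.at_level("WARNING"):
            C, eps = optimize_svr_hyperparams(prob, SVRConfig(seed=0))
        assert (C, eps) == (1.0, 0.1)


class TestSvrSubsampleImportance:
    def test_protocol_counts(self, rng):
        # 200 fits, every r within [ceil(0.2 S), floor(0.8 S)], at most
        # top_k candidates scored per iteration
        prob = _problem(rng, n=100, p=20, noise=0.3)
        cfg = SVRConfig(seed=2)
        totals, details = svr_subsample_importance(
            prob, cfg, hyperparams=(1.0, 0.1), return_details=True
        )
        iters = details["iterations"]
        assert len(iters) == 200
        lo, hi = math.ceil(0.2 * 100), math.floor(0.8 * 100)
        assert all(lo <= it["r"] <= hi for it in iters)
        assert all(len(it["scored"]) <= cfg.top_k for it in iters)
        assert np.all(totals >= 0)

    def test_exactly_dependent_candidate_always_tops(self, rng):
        prob = _problem(rng, n=80, p=3, signal_col=0, noise=0.0)
        totals, details = svr_subsample_importance(
            prob, SVRConfig(seed=4), hyperparams=(1.0, 0.01), return_details=True
        )
        assert all("C1" in it["scored"] for it in details["iterations"])
        assert np.argmax(totals) == 0

    def test_single_candidate_accumulates(self, rng):
        X = rng.standard_normal((50, 1))
        prob = TargetProblem("T", ("C1",), X, X[:, 0].copy())
        totals = svr_subsample_importance(prob, SVRConfig(seed=1), hyperparams=(1.0, 0.01))
        assert totals[0] > 0

    def test_too_few_samples_error(self, rng):
        prob = TargetProblem("T", ("C1",), rng.standard_normal((4, 1)), rng.standard_normal(4))
        with pytest.raises(ValueError, match="5 samples"):
            svr_subsample_importance(prob, SVRConfig(seed=1), hyperparams=(1.0, 0.1))

    def test_deterministic_given_seed(self, rng):
        prob = _problem(rng, noise=0.4)
        cfg = SVRConfig(seed=9, n_iterations=20)
        np.testing.assert_array_equal(
            svr_subsample_importance(prob, cfg, hyperparams=(1.0, 0.1)),
            svr_subsample_importance(prob, cfg, hyperparams=(1.0, 0.1)),
        )

    def test_column_permutation_permutes_totals(self, rng):
        # row subsampling is keyed to the target, not candidate positions,
        # and the top-k tie-break is by candidate name, so reordering the
        # candidate columns reorders the totals (up to solver round-off)
        prob = _problem(rng, p=4, signal_col=1, noise=0.3)
        perm = [2, 0, 3, 1]
        permuted = TargetProblem(
            "T",
            tuple(prob.candidate_ids[i] for i in perm),
            prob.features[:, perm],
            prob.response,
        )
        cfg = SVRConfig(seed=6, n_iterations=30)
        imp = svr_subsample_importance(prob, cfg, hyperparams=(1.0, 0.1))
        imp_perm = svr_subsample_importance(permuted, cfg, hyperparams=(1.0, 0.1))
        np.testing.assert_allclose(imp_perm, imp[perm], rtol=1e-6, atol=1e-8)


@pytest.fixture(scope="module")
def mini():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 3))
    X[:, 2] = X[:, 0] + 0.1 * rng.standard_normal(60)
    expr = ExpressionMatrix(gene_ids=("G1", "G2", "G3"), values=X)
    tfs = RegulatorSet(tf_ids=("G1", "G2"))
    return expr, tfs


class TestScoreAllTargets:

    def test_shape_and_self_exclusion(self, mini):
        expr, tfs = mini
        mat = score_all_targets(expr, tfs, "rfr",
                                TreeRegressorConfig(n_trees=20), master_seed=1)
        assert mat.scores.shape == (2, 3)
        assert mat.entry("G1", "G1") == 0.0
        assert mat.entry("G2", "G2") == 0.0
        assert mat.entry("G1", "G3") > mat.entry("G2", "G3")

    def test_parallel_equals_serial(self, mini):
        expr, tfs = mini
        cfg = TreeRegressorConfig(n_trees=10)
        serial = score_all_targets(expr, tfs, "rfr", cfg, master_seed=3, n_jobs=1)
        parallel = score_all_targets(expr, tfs, "rfr", cfg, master_seed=3, n_jobs=2)
        np.testing.assert_array_equal(serial.scores, parallel.scores)

    def test_per_target_seed_is_name_derived(self):
        assert derive_target_seed(1, "G1") == derive_target_seed(1, "G1")
        assert derive_target_seed(1, "G1") != derive_target_seed(1, "G2")
        assert derive_target_seed(1, "G1") != derive_target_seed(2, "G1")
        assert 0 <= derive_target_seed(123, "X") < 2**31

    def test_error_names_failing_target(self, mini):
        expr, _ = mini
        lone = RegulatorSet(tf_ids=("G1",))
        with pytest.raises(RuntimeError, match="G1"):
            score_all_targets(expr, lone, "rfr", TreeRegressorConfig(n_trees=5))

    def test_method_config_mismatch_rejected(self, mini):
        expr, tfs = mini
        with pytest.raises(ValueError, match="TreeRegressorConfig"):
            score_all_targets(expr, tfs, "rfr", SVRConfig())
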