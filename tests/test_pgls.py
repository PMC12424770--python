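import dendropy
import numpy as np
import pytest

from retroprev import simulate
from retroprev.pgls import (
    aic,
    bh_fdr,
    compare_lambda_models,
    fit_pgls,
    lambda_transform,
    pearson_r,
    prune_tree,
    vcv_from_tree,
    vif,
)


class TestVcv:
    def test_two_tip_star(self):
        t = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        cov = vcv_from_tree(t)
        assert np.allclose(cov.C, np.eye(2))

    def test_three_tip_hand_computed(self, three_tip_tree):
        cov = vcv_from_tree(three_tip_tree, species=["A", "B", "C"])
        assert np.allclose(cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_ultrametric_constant_diagonal(self, yule_cov_50):
        assert np.ptp(np.diag(yule_cov_50.C)) < 1e-9
        # PSD and bounded off-diagonals
        assert np.all(np.linalg.eigvalsh(yule_cov_50.C) > -1e-9)
        C = yule_cov_50.C
        assert np.all(C <= np.minimum.outer(np.diag(C), np.diag(C)) + 1e-12)

    def test_unknown_species_listed(self, three_tip_tree):
        with pytest.raises(KeyError, match="ZZ"):
            vcv_from_tree(three_tip_tree, species=["A", "ZZ"])

    def test_pruning_rebases_at_subset_mrca(self, yule_tree_50, yule_cov_50):
        # pruning re-roots at the subset MRCA: every shared path shrinks by
        # the depth of the dropped stem, uniformly across the matrix
        keep = yule_cov_50.labels[:10]
        sub = vcv_from_tree(yule_tree_50, species=keep)
        full = yule_cov_50.reorder(keep)
        shift = full.C[0, 0] - sub.C[0, 0]
        assert shift >= -1e-12
        assert np.allclose(sub.C, full.C - shift, atol=1e-9)
        pruned = prune_tree(yule_tree_50, keep)
        assert {t.taxon.label for t in pruned.leaf_node_iter()} == set(keep)


class TestLambdaTransform:
    def test_endpoints_and_halving(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(lambda_transform(C, 1.0), C)
        assert np.allclose(lambda_transform(C, 0.0), np.diag([2.0, 2.0]))
        assert lambda_transform(C, 0.5)[0, 1] == 0.5

    def test_out_of_range_rejected(self):
        C = np.eye(2)
        for lam in (-0.1, 1.1):
            with pytest.raises(ValueError):
                lambda_transform(C, lam)


class TestFit:
    def test_noiseless_data_interpolated_exactly(self, yule_cov_50, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = 2.0 * x
        fit = fit_pgls(y, X, yule_cov_50.C)
        assert fit.beta[1] == pytest.approx(2.0, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)

    def test_lambda0_equal_weights_matches_ols(self, yule_cov_50, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.5] + rng.standard_normal(n)
        fit = fit_pgls(y, X, yule_cov_50.C, lambda_mode="fixed_0")
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(fit.beta - ols).max() < 1e-8

    def test_lambda1_no_weights_matches_direct_gls(self, yule_cov_50, rng):
        n = 50
        C = yule_cov_50.C
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate.simulate_traits(C, 1.0, 1.0, [0.0, 1.0], X, None, seed=5)
        fit = fit_pgls(y, X, C, lambda_mode="fixed_1")
        Ci = np.linalg.inv(C)
        gls = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert np.abs(fit.beta - gls).max() < 1e-8

    def test_rank_deficient_design_rejected(self, yule_cov_50, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            fit_pgls(rng.standard_normal(n), X, yule_cov_50.C)

    def test_aic_bookkeeping(self, yule_cov_50, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate.simulate_traits(yule_cov_50.C, 0.5, 1.0, [0.0, 1.0], X, None, seed=9)
        est = fit_pgls(y, X, yule_cov_50.C)
        fixed = fit_pgls(y, X, yule_cov_50.C, lambda_mode="fixed_1")
        assert est.k_params == 4 and fixed.k_params == 3  # beta(2) + sigma2 (+ lambda)
        assert est.aic == pytest.approx(-2 * est.loglik + 2 * est.k_params)
        # weighted default adds the tau^2 scale parameter
        w = rng.uniform(0.05, 0.2, n)
        west = fit_pgls(y, X, yule_cov_50.C, weights=w)
        assert west.k_params == 5 and west.tau2_hat is not None

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_likelihood_nesting(self, yule_cov_50, rng, seed):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = simulate.simulate_traits(
            yule_cov_50.C, 0.6, 1.0, [0.0, 0.5], X, None, seed=seed
        )
        est = fit_pgls(y, X, yule_cov_50.C, compute_diagnostics=False)
        for mode in ("fixed_0", "fixed_1"):
            fixed = fit_pgls(y, X, yule_cov_50.C, lambda_mode=mode,
                             compute_diagnostics=False)
            assert est.loglik >= fixed.loglik - 1e-6

    def test_strict_error_scale_mode(self, yule_cov_50, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        w = rng.uniform(0.1, 0.4, n)
        y = simulate.simulate_traits(yule_cov_50.C, 0.5, 1.0, [0.0, 1.0], X, w, seed=2)
        fit = fit_pgls(y, X, yule_cov_50.C, weights=w, error_scale="fixed")
        assert fit.tau2_hat == 1.0
        assert 0.0 <= fit.lambda_hat <= 1.0 and fit.sigma2_hat > 0


class TestCompareLambda:
    def test_boundary_estimate_matches_fixed_loglik(self, yule_cov_50, rng):
        # on lambda=0 data the estimate usually hits the boundary exactly
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        hit = 0
        for seed in range(5):
            y = simulate.simulate_traits(
                yule_cov_50.C, 0.0, 1.0, [0.0, 0.5], X, None, seed=seed
            )
            tab = compare_lambda_models(y, X, yule_cov_50.C)
            row = tab.set_index("model")
            assert row.loc["lambda_hat", "loglik"] >= row.loc["lambda_0", "loglik"] - 1e-6
            assert row.loc["lambda_hat", "loglik"] >= row.loc["lambda_1", "loglik"] - 1e-6
            if row.loc["lambda_hat", "lambda"] == 0.0:
                hit += 1
                assert row.loc["lambda_hat", "loglik"] == pytest.approx(
                    row.loc["lambda_0", "loglik"], abs=1e-8
                )
        assert hit >= 3

    def test_bm_data_penalizes_lambda0(self, yule_cov_50, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        worst_is_0 = 0
        for seed in range(5):
            y = simulate.simulate_traits(
                yule_cov_50.C, 1.0, 1.0, [0.0, 0.5], X, None, seed=100 + seed
            )
            tab = compare_lambda_models(y, X, yule_cov_50.C).set_index("model")
            worst_is_0 += tab["aic"].idxmax() == "lambda_0"
        assert worst_is_0 >= 4


def test_aic_formula():
    assert aic(0.0, 2) == 4.0
    assert aic(-10.0, 3) == 26.0
    assert aic(5.0, 3) - aic(5.0, 2) == 2.0
    with pytest.raises(ValueError):
        aic(0.0, 0)


class TestBhFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_step_up_hand_example(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        adj, rej = bh_fdr([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0) and not np.any(rej)

    def test_adjusted_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=25)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        assert np.allclose(vif(np.column_stack([x1, x2])), 1.0)

    def test_near_collinear_exceeds_threshold(self, rng):
        x1 = rng.standard_normal(100)
        x2 = x1 + 1e-4 * rng.standard_normal(100)
        v = vif(np.column_stack([x1, x2]))
        assert np.all(v > 5)
        # cross-check against direct auxiliary-regression R^2
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        assert v[0] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_duplicated_predictor_infinite(self, rng):
        x = rng.standard_normal(30)
        v = vif(np.column_stack([x, x]))
        assert np.all(np.isinf(v))


class TestPearson:
    def test_exact_lines(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(777)
        assert abs(pearson_r(rng.standard_normal(10_000), rng.standard_normal(10_000))) < 0.05

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
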