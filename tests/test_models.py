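"""Fold plans, cross-validated R^2, causal-fraction selection, and the
elastic-net solver (closed forms, brute-force oracle, grouping, tuning)."""

import numpy as np
import pytest
from scipy import optimize

from mpspred import models
from mpspred.models import (
    cv_r2,
    enet_fit,
    enet_objective,
    enet_tune,
    lambda_max,
    make_fold_plan,
    select_best_fraction,
)


class TestFoldPlan:
    def test_balanced_folds(self):
        plan = make_fold_plan(100, k=10, repeats=2, seed=0)
        for r in range(2):
            sizes = np.bincount(plan.assignments[r], minlength=10)
            assert np.all(sizes == 10)

    def test_remainder_rule(self):
        plan = make_fold_plan(103, k=10, repeats=1, seed=0)
        sizes = sorted(np.bincount(plan.assignments[0]), reverse=True)
        assert sizes == [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]

    def test_determinism_and_partition(self):
        a = make_fold_plan(57, k=5, repeats=3, seed=7)
        b = make_fold_plan(57, k=5, repeats=3, seed=7)
        assert np.array_equal(a.assignments, b.assignments)
        for _r, _f, tr, va in a.folds():
            assert len(np.intersect1d(tr, va)) == 0
            assert len(tr) + len(va) == 57

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(5, k=10)


class TestCvR2:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        plan = make_fold_plan(200, k=10, repeats=1, seed=1)
        mean, dist = cv_r2(x, x.copy(), plan)
        assert mean > 0.99
        assert len(dist) == 10

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = rng.normal(size=500)
        plan = make_fold_plan(500, k=10, repeats=5, seed=2)
        mean, _ = cv_r2(x, y, plan)
        # squared-correlation R^2 has positive bias ~1/(n_fold - 1) under null
        assert mean < 0.03

    def test_known_population_r2_recovered(self):
        """y = x + noise with Var(x) = Var(noise): population R^2 = 0.5."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        y = x + rng.normal(size=2000)
        plan = make_fold_plan(2000, k=10, repeats=2, seed=3)
        mean, _ = cv_r2(x, y, plan)
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_missing_values_rejected(self):
        plan = make_fold_plan(10, k=2)
        x = np.ones(10)
        x[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cv_r2(x, np.arange(10.0), plan)


class TestSelectBestFraction:
    def test_exact_predictor_wins(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=120)
        plan = make_fold_plan(120, k=10, seed=4)
        variants = {1.0: rng.normal(size=120), 0.1: y.copy(), 0.01: rng.normal(size=120)}
        res = select_best_fraction(variants, y, plan)
        assert res.chosen_fraction == 0.1
        assert res.cv_r2 > 0.99

    def test_tie_breaks_to_sparsest_prior(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=100)
        y = col + rng.normal(size=100)
        plan = make_fold_plan(100, k=5, seed=5)
        res = select_best_fraction({1.0: col, 0.1: col.copy(), 0.01: col.copy()}, y, plan)
        assert res.chosen_fraction == 0.01

    def test_selected_regression_coefficients(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 2.0 * x + 1.0 + rng.normal(scale=0.01, size=200)
        plan = make_fold_plan(200, k=5, seed=6)
        res = select_best_fraction({1.0: x}, y, plan)
        assert res.slope == pytest.approx(2.0, abs=0.01)
        assert res.intercept == pytest.approx(1.0, abs=0.01)

    def test_sparse_architecture_prefers_sparse_prior(self):
        """When only ~1% of SNPs are causal, the sparse-prior score variant is
        selected in at least 8 of 10 seeded replicates."""
        from mpspred.scoring import estimate_ld, shrink_gibbs, shrink_infinitesimal
        from mpspred.simulate import (
            SimulationConfig,
            simulate_effect_sizes,
            simulate_genotypes,
            simulate_ld_structure,
            simulate_sumstats,
        )

        wins = 0
        for seed in range(10):
            m, n_tgt, n_gwas, h2 = 500, 600, 50_000, 0.5
            ld_true = simulate_ld_structure(m, 10, 0.5)
            cfg = SimulationConfig(n_snps=m, n_blocks=10, block_rho=0.5, n_traits=1,
                                   genetic_corr=np.eye(1), h2=h2, causal_fraction=0.01,
                                   gwas_n=n_gwas, target_n=n_tgt, seed=seed,
                                   outcome_weights=np.array([1.0]), outcome_noise_var=0.5)
            panel = simulate_genotypes(n_tgt, ld_true, seed=seed + 50)
            eff = simulate_effect_sizes(cfg, ld=ld_true)
            tab = simulate_sumstats(eff, ld_true, n_gwas, seed=seed + 60, panel=panel)[0]
            beta_hat = tab["BETA"].to_numpy()
            x = panel.standardized()
            g = x @ eff.beta_true[0]
            rng = np.random.default_rng(seed + 70)
            y = g + rng.normal(scale=g.std(), size=n_tgt)
            ld_est = estimate_ld(panel, 50)
            variants = {}
            for p in (1.0, 0.1, 0.01):
                if p == 1.0:
                    w = shrink_infinitesimal(beta_hat, ld_est, n_gwas, h2).weights
                else:
                    w = shrink_gibbs(beta_hat, ld_est, n_gwas, h2, fraction_p=p,
                                     iters=300, burn_in=60, seed=seed).weights
                variants[p] = x @ w
            plan = make_fold_plan(n_tgt, k=5, repeats=2, seed=seed)
            res = select_best_fraction(variants, y, plan)
            wins += res.chosen_fraction <= 0.1
        assert wins >= 8


class TestEnetObjective:
    def test_null_model_loss_is_half_variance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=50)
        x = rng.normal(size=(50, 3))
        loss = enet_objective(np.zeros(3), y.mean(), x, y, alpha=0.5, lam=1.0)
        assert loss == pytest.approx(0.5 * y.var())

    def test_lambda_zero_is_least_squares(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        x = rng.normal(size=(30, 2))
        b = np.array([0.3, -0.2])
        expected = 0.5 * np.mean((y - x @ b) ** 2)
        assert enet_objective(b, 0.0, x, y, 0.7, 0.0) == pytest.approx(expected)

    def test_hand_computed_three_point_example(self):
        x = np.array([[1.0], [0.0], [-1.0]])
        y = np.array([1.0, 0.0, -1.0])
        loss = enet_objective(np.array([0.5]), 0.0, x, y, alpha=1.0, lam=0.1)
        assert loss == pytest.approx(1 / 6 * 0.5 + 0.05)  # 0.13333...

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            enet_objective(np.zeros(1), 0, np.ones((2, 1)), np.ones(2), alpha=1.5, lam=0.1)
        with pytest.raises(ValueError):
            enet_objective(np.zeros(1), 0, np.ones((2, 1)), np.ones(2), alpha=0.5, lam=-1)


def standardize(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


class TestEnetFit:
    def test_lambda_zero_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        x = standardize(rng.normal(size=(100, 4)))
        y = x @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(size=100)
        fit = enet_fit(x, y, alpha=0.5, lam=0.0, tol=1e-10)
        design = np.column_stack([np.ones(100), x])
        ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.abs(fit.coef - ols[1:]).max() < 1e-6
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_orthonormal_lasso_soft_threshold_closed_form(self):
        """With orthonormal columns ((1/n) X'X = I) and alpha = 1, each
        coefficient is the soft-thresholded OLS estimate."""
        rng = np.random.default_rng(9)
        n, m = 200, 5
        x = rng.normal(size=(n, m))
        x = x - x.mean(axis=0)
        gram = x.T @ x / n
        x = x @ np.linalg.inv(np.linalg.cholesky(gram)).T  # (1/n) x'x = I exactly
        y = rng.normal(size=n)
        lam = 0.05
        fit = enet_fit(x, y, alpha=1.0, lam=lam, tol=1e-12)
        beta_ols = x.T @ (y - y.mean()) / n
        expected = np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0)
        assert np.abs(fit.coef - expected).max() < 1e-8

    def test_lambda_max_gives_all_zero(self):
        rng = np.random.default_rng(10)
        x = standardize(rng.normal(size=(80, 6)))
        y = x[:, 0] + rng.normal(size=80)
        for alpha in (0.3, 1.0):
            lmax = lambda_max(x, y, alpha)
            assert np.all(enet_fit(x, y, alpha, lmax).coef == 0)
            assert np.any(enet_fit(x, y, alpha, 0.95 * lmax).coef != 0)

    def test_objective_non_increasing_every_sweep(self):
        rng = np.random.default_rng(11)
        x = standardize(rng.normal(size=(60, 10)))
        y = rng.normal(size=60)
        fit = enet_fit(x, y, alpha=0.5, lam=0.01, track_objective=True)
        obj = fit.objective_path
        assert np.all(np.diff(obj) <= 1e-12)

    def test_grouping_effect_duplicate_columns(self):
        """Duplicated predictors get equal coefficients for any alpha < 1."""
        rng = np.random.default_rng(12)
        col = rng.normal(size=150)
        col = (col - col.mean()) / col.std()
        x = np.column_stack([col, col, standardize(rng.normal(size=(150, 1)))])
        y = 2 * col + rng.normal(size=150)
        fit = enet_fit(x, y, alpha=0.5, lam=0.1, tol=1e-12)
        assert fit.coef[0] == pytest.approx(fit.coef[1], abs=1e-6)
        assert fit.coef[0] > 0

    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.05), (0.5, 0.1), (0.0, 0.2), (0.8, 0.02)])
    def test_matches_sklearn(self, alpha, lam):
        """Independent cross-check against scikit-learn's coordinate descent
        (same objective parameterization)."""
        from sklearn.linear_model import ElasticNet, Ridge

        rng = np.random.default_rng(13)
        x = standardize(rng.normal(size=(120, 8)))
        y = x @ rng.normal(size=8) * 0.3 + rng.normal(size=120)
        fit = enet_fit(x, y, alpha, lam, tol=1e-12)
        if alpha == 0.0:
            ref = Ridge(alpha=lam * len(y), fit_intercept=True).fit(x, y)
        else:
            ref = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                             tol=1e-12, max_iter=100_000).fit(x, y)
        assert np.abs(fit.coef - ref.coef_).max() < 1e-5

    def test_brute_force_oracle_small_instances(self):
        """Objective value within 1e-4 of a direct numerical minimizer on
        random instances with <= 8 predictors."""
        rng = np.random.default_rng(14)
        for trial in range(10):
            n = int(rng.integers(30, 80))
            m = int(rng.integers(1, 9))
            x = standardize(rng.normal(size=(n, m)))
            y = x @ rng.normal(size=m) + rng.normal(size=n)
            alpha = float(rng.uniform())
            lam = float(rng.uniform(0.001, 0.5))
            fit = enet_fit(x, y, alpha, lam, tol=1e-12)
            yc = y - y.mean()
            obj_cd = enet_objective(fit.coef, 0.0, x, yc, alpha, lam)
            res = optimize.minimize(
                lambda b: enet_objective(b, 0.0, x, yc, alpha, lam),
                np.zeros(m), method="Nelder-Mead",
                options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
            assert obj_cd <= res.fun + 1e-4


class TestEnetTune:
    def test_signal_columns_retained_with_grouping(self):
        """y built from 2 of 40 correlated score columns: the tuned model
        retains a superset including both in >= 8/10 seeded replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, m = 300, 40
            base = rng.normal(size=(n, m)) + 0.5 * rng.normal(size=(n, 1))
            x = standardize(base)
            y = x[:, 3] + x[:, 17] + rng.normal(size=n)
            plan = make_fold_plan(n, k=5, repeats=1, seed=seed)
            fit = enet_tune(x, y, plan, alpha_grid=(0.5, 1.0), n_lambda=30)
            hits += {3, 17} <= set(fit.retained)
        assert hits >= 8

    def test_pure_noise_selects_near_empty_model(self):
        empties = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = standardize(rng.normal(size=(200, 20)))
            y = rng.normal(size=200)
            plan = make_fold_plan(200, k=5, repeats=1, seed=seed)
            fit = enet_tune(x, y, plan, alpha_grid=(0.5, 1.0), n_lambda=20)
            empties += len(fit.retained) <= 2
        assert empties >= 8

    def test_ridge_only_path_keeps_all_coefficients(self):
        rng = np.random.default_rng(15)
        x = standardize(rng.normal(size=(100, 5)))
        y = x @ np.array([1.0, 0.5, -0.5, 0.2, -0.2]) + rng.normal(size=100)
        plan = make_fold_plan(100, k=5, repeats=1, seed=0)
        fit = enet_tune(x, y, plan, alpha_grid=(0.0,), n_lambda=10)
        assert np.all(fit.coef != 0)

    def test_cv_distribution_attached_and_selection_consistent(self):
        """The tuned multi-score model's training CV cannot be meaningfully
        worse than the best of its own single columns."""
        rng = np.random.default_rng(16)
        n = 250
        x = standardize(rng.normal(size=(n, 6)))
        y = 0.8 * x[:, 0] + 0.4 * x[:, 1] + rng.normal(size=n)
        plan = make_fold_plan(n, k=5, repeats=2, seed=1)
        fit = enet_tune(x, y, plan, alpha_grid=(0.0, 0.5, 1.0), n_lambda=30)
        assert fit.cv_r2_distribution is not None
        assert len(fit.cv_r2_distribution) == 10
        best_single = max(cv_r2(x[:, j], y, plan)[0] for j in range(6))
        assert fit.cv_r2_mean >= best_single - 0.005

    def test_empty_grid_rejected(self):
        plan = make_fold_plan(50, k=5)
        with pytest.raises(ValueError):
            enet_tune(np.ones((50, 2)), np.arange(50.0), plan, alpha_grid=(), n_lambda=10)
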