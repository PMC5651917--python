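"""REML variance components, Henderson BLUE/BLUP and held-out prediction."""

import warnings

import numpy as np
import pytest

from gsherit import (MixedModelData, VarianceComponents, compute_kinship,
                     henderson_solve, heritability, panel_data,
                     predict_holdout, reml_fit, reml_loglik, rescale_kinship,
                     simulate_phenotypes)

from conftest import make_panel, random_genotypes, sigma_for_signal
from oracles import dense_loglik, dense_loglik_grid


def _instance(rng, n=15, m=60, signal=0.5):
    """Small random panel + trait with an interior REML optimum."""
    geno = random_genotypes(rng, n, m)
    K = rescale_kinship(compute_kinship(geno))
    sg = sigma_for_signal(signal, m)
    gamma = rng.normal(0, sg, m)
    y = geno.values.astype(float) @ gamma + rng.normal(0, 1.0, n)
    return MixedModelData(y, K)


class TestRemlFit:
    def test_matches_dense_grid_oracle_small(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            data = _instance(rng, n=14, m=80)
            vc = reml_fit(data)
            vy = data.y.var(ddof=1)
            grid = np.linspace(1e-4, 10 * vy, 60)
            surface = dense_loglik_grid(data.y, data.X, data.K.values,
                                        grid, grid)
            assert vc.loglik >= surface.max() - 1e-6
            i, j = np.unravel_index(np.argmax(surface), surface.shape)
            cell = grid[1] - grid[0]
            assert abs(vc.sigma_A2 - grid[i]) <= cell
            assert abs(vc.sigma2 - grid[j]) <= cell

    def test_loglik_consistent_with_dense_evaluation(self):
        rng = np.random.default_rng(1)
        data = _instance(rng)
        vc = reml_fit(data)
        assert vc.loglik == pytest.approx(
            dense_loglik(data.y, data.X, data.K.values, vc.sigma_A2,
                         vc.sigma2), abs=1e-8)
        # ML objective differs from REML by the X'V^-1X determinant term
        vc_ml = reml_fit(data, method="ML")
        assert vc_ml.method == "ML"
        assert vc_ml.loglik == pytest.approx(
            dense_loglik(data.y, data.X, data.K.values, vc_ml.sigma_A2,
                         vc_ml.sigma2, method="ML"), abs=1e-8)

    def test_optimum_at_least_as_good_as_naive_start(self):
        rng = np.random.default_rng(2)
        data = _instance(rng)
        vc = reml_fit(data)
        vy = data.y.var(ddof=1)
        assert vc.loglik >= reml_loglik(data, vy / 2, vy / 2) - 1e-9

    def test_pure_noise_pins_sigma_a2_in_majority_of_draws(self):
        rng = np.random.default_rng(3)
        pinned = 0
        draws = 30
        for _ in range(draws):
            geno = random_genotypes(rng, 50, 500)
            K = rescale_kinship(compute_kinship(geno))
            y = rng.normal(size=50)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vc = reml_fit(MixedModelData(y, K))
            pinned += vc.sigma_A2 <= 2e-5
        assert pinned > draws / 2

    def test_constant_y_rejected(self, small_data):
        data = MixedModelData(np.ones(small_data.n), small_data.K)
        with pytest.raises(ValueError, match="constant"):
            reml_fit(data)

    def test_identity_kinship_flags_flat_likelihood(self):
        from gsherit import KinshipMatrix
        rng = np.random.default_rng(4)
        n = 30
        K = KinshipMatrix(np.eye(n), tuple(f"i{j}" for j in range(n)),
                          rescaled=True)
        with pytest.warns(RuntimeWarning, match="flat"):
            vc = reml_fit(MixedModelData(rng.normal(size=n), K))
        assert vc.degenerate

    def test_lambda_consistency(self):
        rng = np.random.default_rng(5)
        vc = reml_fit(_instance(rng))
        assert vc.lam == pytest.approx(vc.sigma_A2 / vc.sigma2, rel=1e-10)


class TestHendersonSolve:
    def test_two_routes_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            data = _instance(rng, n=12, m=50)
            vc = reml_fit(data)
            a = henderson_solve(data, vc, route="henderson")
            b = henderson_solve(data, vc, route="gls")
            np.testing.assert_allclose(a.beta_hat, b.beta_hat, rtol=1e-8)
            np.testing.assert_allclose(a.xi_hat, b.xi_hat, rtol=1e-8,
                                       atol=1e-10)

    def test_solution_satisfies_block_system(self):
        rng = np.random.default_rng(7)
        data = _instance(rng, n=12, m=50)
        vc = reml_fit(data)
        fit = henderson_solve(data, vc)
        K_inv = np.linalg.inv(data.K.values)
        X, y, n = data.X, data.y, data.n
        M = np.block([[X.T @ X, X.T], [X, np.eye(n) + K_inv / vc.lam]])
        rhs = np.concatenate([X.T @ y, y])
        sol = np.concatenate([fit.beta_hat, fit.xi_hat])
        resid = M @ sol - rhs
        assert np.linalg.norm(resid) <= 1e-6 * np.linalg.norm(rhs)

    def test_infinite_shrinkage_limit_is_ols(self, small_data):
        vc = VarianceComponents(sigma_A2=1e-12, sigma2=1.0)
        fit = henderson_solve(small_data, vc)
        ols = np.linalg.lstsq(small_data.X, small_data.y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta_hat, ols, rtol=1e-8)
        assert np.abs(fit.xi_hat).max() < 1e-9

    def test_gls_estimating_equation(self, small_data):
        vc = reml_fit(small_data)
        fit = henderson_solve(small_data, vc)
        V = vc.sigma_A2 * small_data.K.values + vc.sigma2 * np.eye(small_data.n)
        resid = small_data.y - small_data.X @ fit.beta_hat
        score = small_data.X.T @ np.linalg.solve(V, resid)
        np.testing.assert_allclose(score, 0, atol=1e-8)

    def test_singular_kinship_reported_on_henderson_route(self):
        rng = np.random.default_rng(8)
        data = _instance(rng, n=20, m=5)  # m < n, K rank deficient
        vc = VarianceComponents(sigma_A2=1.0, sigma2=1.0)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            henderson_solve(data, vc, route="henderson")
        henderson_solve(data, vc, route="gls")  # GLS route still fine


class TestPredictHoldout:
    def test_unrelated_test_rows_predict_fixed_effects_only(self):
        from gsherit import KinshipMatrix
        rng = np.random.default_rng(9)
        n = 12
        K = np.eye(n)
        K[:8, :8] += 0.3  # related training block; test rows unrelated
        K[-1, :8] = K[:8, -1] = 0.0
        data = MixedModelData(rng.normal(size=n),
                              KinshipMatrix(K, tuple(f"i{j}" for j in range(n))))
        vc = VarianceComponents(sigma_A2=0.7, sigma2=0.5)
        pred = predict_holdout(data, np.arange(8), np.array([n - 1]), vc)
        beta = pred.beta_hat
        assert pred.xi2_hat[0] == pytest.approx(0.0, abs=1e-12)
        assert pred.y2_hat[0] == pytest.approx(float(beta[0]))

    def test_duplicated_individual_recovers_training_blup(self):
        # a test line with a genotype row identical to a training line has
        # identical kinship rows, so its prediction equals that line's BLUP
        rng = np.random.default_rng(10)
        geno = random_genotypes(rng, 20, 100)
        values = np.vstack([geno.values, geno.values[0]])
        from gsherit import GenotypeMatrix
        full = GenotypeMatrix(values,
                              tuple(f"i{j}" for j in range(21)),
                              geno.locus_ids)
        K = rescale_kinship(compute_kinship(full))
        y = rng.normal(size=21)
        data = MixedModelData(y, K)
        vc = VarianceComponents(sigma_A2=1.0, sigma2=0.3)
        train = np.arange(20)
        pred = predict_holdout(data, train, np.array([20]), vc)
        train_fit = henderson_solve(data.subset(train), vc)
        assert pred.xi2_hat[0] == pytest.approx(train_fit.xi_hat[0], rel=1e-10)

    def test_accuracy_increases_with_signal(self):
        gmap_panel = make_panel(n=120, n_loci=300, seed=11)
        rng = np.random.default_rng(12)
        train = np.arange(90)
        test = np.arange(90, 120)
        acc = []
        for i, ratio in enumerate((1 / 50, 1 / 20, 1 / 10)):
            pheno, _ = simulate_phenotypes(gmap_panel, ratio, 1.0,
                                           replicates=1, seed=13 + i)
            y = pheno.values_for(gmap_panel.individual_ids)
            data = panel_data(gmap_panel, y)
            vc = reml_fit(data.subset(train))
            pred = predict_holdout(data, train, test, vc)
            xi_true = pheno.genetic_values.to_numpy()[test]
            acc.append(np.corrcoef(pred.xi2_hat, xi_true)[0, 1] ** 2)
        assert acc[0] < acc[1] < acc[2]
        assert acc[2] > 0

    def test_overlap_and_empty_sets_rejected(self, small_data):
        vc = VarianceComponents(sigma_A2=1.0, sigma2=1.0)
        with pytest.raises(ValueError, match="overlap"):
            predict_holdout(small_data, np.arange(10), np.arange(5, 12), vc)
        with pytest.raises(ValueError, match="nonempty"):
            predict_holdout(small_data, np.arange(10), np.array([]), vc)


class TestHeritability:
    @pytest.mark.parametrize("sa2, s2, expected", [
        (17.63, 11.80, 0.60),   # yield
        (10.63, 0.55, 0.95),    # grain weight
        (2.17, 0.37, 0.85),     # tiller number
        (647.85, 126.56, 0.84), # grain number
    ])
    def test_rice_variance_component_arithmetic(self, sa2, s2, expected):
        assert round(heritability(sa2, s2), 2) == expected

    def test_trivial_values(self):
        assert heritability(0.0, 1.0) == 0.0
        assert heritability(1.0, 1.0) == 0.5

    def test_monotone_in_genetic_variance(self):
        grid = np.linspace(0, 5, 20)
        h = [heritability(a, 1.3) for a in grid]
        assert all(x < y for x, y in zip(h, h[1:]))
        assert all(0 <= x <= 1 for x in h)

    def test_accepts_varcomp_object(self):
        vc = VarianceComponents(sigma_A2=3.0, sigma2=1.0)
        assert heritability(vc) == pytest.approx(0.75)
        assert vc.h2 == pytest.approx(0.75)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0)
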