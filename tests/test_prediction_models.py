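"""Mixed-model, Bayesian regression, kernel, and forest fits."""

import numpy as np
import pandas as pd
import pytest

from hybridgs import (
    ModelSpec,
    SimConfig,
    additive_kinship,
    dominance_kinship,
    fit_gblup,
    fit_markers_bayesB,
    fit_markers_blasso,
    fit_rkhs,
    fit_tree_ensemble,
    gaussian_kernel,
    heterozygosity_design,
    predict_gblup,
    predict_markers,
    simulate_breeding_population,
)
from hybridgs.prediction_models import _reml_loglik
from hybridgs.relationship_matrices import KinshipMatrix

from conftest import make_matrix

MCMC_SMALL = {"n_iter": 3000, "burn_in": 1000, "thin": 2, "seed": 7}


def _series(values, prefix="i", name="trait"):
    return pd.Series(values, index=[f"{prefix}{k}" for k in range(len(values))],
                     name=name)


@pytest.fixture(scope="module")
def inbred_G(small_sim):
    return small_sim.G_inbreds


class TestGBLUPReml:
    def test_noiseless_limit_reproduces_y(self):
        """y drawn exactly from N(1 mu, A) with a rank-deficient A: REML
        drives sigma2_e to zero and the BLUP interpolates y."""
        rng = np.random.default_rng(0)
        n, m = 50, 30  # m < n so draws lie in a proper subspace
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        Xc = X - X.mean(axis=0)
        A = KinshipMatrix([f"i{k}" for k in range(n)], Xc @ Xc.T / (m / 2),
                          "additive")
        s, U = np.linalg.eigh(A.values)
        s = np.clip(s, 0.0, None)
        y = pd.Series(1.5 + U @ (np.sqrt(s) * rng.standard_normal(n)),
                      index=A.ids, name="t")
        fit = fit_gblup(y, A)
        assert np.abs(fit.fitted_values - y).max() < 1e-6
        vc = fit.components
        assert vc.sigma2_e / vc.sigma2_A < 1e-6

    def test_reml_matches_grid_search_oracle(self, small_sim):
        """Profile-REML optimum agrees with a brute-force 2-d likelihood
        grid to 3 significant figures on a 50-line instance."""
        rng = np.random.default_rng(1)
        A = additive_kinship(small_sim.G_inbreds)
        n = A.n
        g = np.linalg.cholesky(A.values + 1e-8 * np.eye(n)) @ \
            rng.standard_normal(n)
        y = pd.Series(2.0 + g + rng.normal(0, 0.6, n), index=A.ids, name="t")
        fit = fit_gblup(y, A)
        vc = fit.components
        # coarse-to-fine grid oracle over (sigma2_A, sigma2_e)
        best, argbest = -np.inf, None
        ga = np.linspace(max(vc.sigma2_A * 0.5, 1e-3), vc.sigma2_A * 1.5, 200)
        ge = np.linspace(max(vc.sigma2_e * 0.5, 1e-3), vc.sigma2_e * 1.5, 200)
        for a_ in ga:
            for e_ in ge:
                ll = _reml_loglik(y.to_numpy(), [a_, e_], [A.values])
                if ll > best:
                    best, argbest = ll, (a_, e_)
        assert vc.sigma2_A == pytest.approx(argbest[0], rel=5e-3)
        assert vc.sigma2_e == pytest.approx(argbest[1], rel=5e-3)

    def test_parameter_recovery_h2_06(self):
        """Mean REML h2 over 20 simulated additive traits at n = 200 is
        within 0.6 +/- 0.1 of the generating value."""
        cfg = SimConfig(n_markers=400, n_lines=70, intercross_size=100,
                        n_crosses=200, seed=21)
        sim = simulate_breeding_population(cfg)
        from hybridgs.synthetic_data import (TraitArchitecture,
                                             assign_trait_architecture,
                                             simulate_phenotypes)
        arch = TraitArchitecture("t", n_qtl=80, sigma2_A=0.6, sigma2_D=0.0,
                                 sigma2_e=0.4)
        A = additive_kinship(sim.G_f1)
        h2s = []
        for rep in range(20):
            truth = assign_trait_architecture(sim.G_f1, arch, seed=100 + rep)
            y = simulate_phenotypes(truth, 0.4, seed=200 + rep)
            vc = fit_gblup(y, A).components
            h2s.append(vc.sigma2_A / (vc.sigma2_A + vc.sigma2_e))
        assert abs(np.mean(h2s) - 0.6) < 0.1

    def test_gibbs_engine_reproducible_and_consistent(self, inbred_G):
        rng = np.random.default_rng(3)
        A = additive_kinship(inbred_G)
        g = np.linalg.cholesky(A.values + 1e-8 * np.eye(A.n)) @ \
            rng.standard_normal(A.n)
        y = pd.Series(g + rng.normal(0, 0.5, A.n), index=A.ids, name="t")
        spec = ModelSpec("GBLUP", hyperparameters=MCMC_SMALL)
        f1 = fit_gblup(y, A, engine="Gibbs", spec=spec)
        f2 = fit_gblup(y, A, engine="Gibbs", spec=spec)
        assert np.allclose(f1.fitted_values, f2.fitted_values)
        # Gibbs posterior means near the REML point estimate
        f3 = fit_gblup(y, A, engine="REML")
        r = np.corrcoef(f1.fitted_values, f3.fitted_values)[0, 1]
        assert r > 0.98


class TestRidgeDuality:
    def test_gblup_equals_ridge_regression(self):
        """With A = X X' / c, GBLUP BLUPs equal ridge-regression
        predictions with lambda = sigma2_e / sigma2_beta, to 1e-6."""
        rng = np.random.default_rng(5)
        n, m = 30, 500
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m))
        X = X - X.mean(axis=0)
        c = m / 4.0
        A = KinshipMatrix([f"i{k}" for k in range(n)], X @ X.T / c, "additive")
        y = pd.Series(rng.standard_normal(n), index=A.ids, name="t")
        fit = fit_gblup(y, A)
        vc = fit.components
        sigma2_beta = vc.sigma2_A / c
        lam = vc.sigma2_e / sigma2_beta
        beta = np.linalg.solve(X.T @ X + lam * np.eye(m),
                               X.T @ (y.to_numpy() - fit.mu))
        ridge_fitted = fit.mu + X @ beta
        assert np.abs(ridge_fitted - fit.fitted_values.to_numpy()).max() < 1e-6


class TestPredictGBLUP:
    def test_test_equals_train_gives_fitted_values(self, inbred_G):
        rng = np.random.default_rng(6)
        A = additive_kinship(inbred_G)
        y = pd.Series(rng.standard_normal(A.n), index=A.ids, name="t")
        fit = fit_gblup(y, A)
        pred = predict_gblup(fit, A, test_ids=list(y.index))
        assert np.allclose(pred, fit.fitted_values, atol=1e-8)

    def test_unrelated_individual_predicted_at_mu(self):
        ids = [f"i{k}" for k in range(11)]
        K = np.eye(11)
        K[:10, :10] += 0.5
        A = KinshipMatrix(ids, K, "additive")
        rng = np.random.default_rng(7)
        y = pd.Series(3.0 + rng.standard_normal(10), index=ids[:10], name="t")
        fit = fit_gblup(y, A)
        pred = predict_gblup(fit, A, test_ids=["i10"])
        assert pred.iloc[0] == pytest.approx(fit.mu, abs=1e-8)

    def test_dominance_flavor_mismatch_raises(self, inbred_G):
        A = additive_kinship(inbred_G)
        D = dominance_kinship(inbred_G)
        y = pd.Series(np.arange(A.n, dtype=float), index=A.ids, name="t")
        fit = fit_gblup(y, A, D)
        with pytest.raises(ValueError, match="dominance"):
            predict_gblup(fit, A, None, test_ids=A.ids[:3])


class TestBayesB:
    def test_planted_qtl_ranked_top(self):
        """5 planted QTL rank in the top 5% by |posterior mean| in
        >= 8 of 10 replicates (h2 = 0.8, n = 300, sparse)."""
        n, m = 300, 200
        wins = 0
        for rep in range(10):
            rng = np.random.default_rng(30 + rep)
            X = rng.choice([-1.0, 0.0, 1.0], size=(n, m), p=[0.45, 0.1, 0.45])
            qtl = rng.choice(m, 5, replace=False)
            beta = np.zeros(m)
            # effects bounded away from zero so every QTL is detectable
            beta[qtl] = rng.uniform(0.5, 1.5, 5) * rng.choice([-1, 1], 5)
            g = X @ beta
            g *= np.sqrt(0.8 / g.var())
            y = _series(g + rng.normal(0, np.sqrt(0.2), n))
            # prior odds matched to the sparse architecture
            fit = fit_markers_bayesB(
                y, X, spec=ModelSpec("BayesB", hyperparameters=dict(
                    MCMC_SMALL, pi=0.99)))
            top = np.argsort(-np.abs(fit.beta_add))[: max(int(0.05 * m), 5)]
            if len(set(top) & set(qtl)) == 5:
                wins += 1
        assert wins >= 8

    def test_noise_effects_shrink_relative_to_planted_qtl(self):
        """Pure-noise fits produce much smaller max effects than a fit
        with a planted 1-SD QTL, consistently over 10 replicates."""
        n, m = 150, 200
        smaller = 0
        for rep in range(10):
            rng = np.random.default_rng(60 + rep)
            X = rng.choice([-1.0, 1.0], size=(n, m))
            y_noise = _series(rng.standard_normal(n))
            spec = ModelSpec("BayesB", hyperparameters=dict(
                MCMC_SMALL, seed=rep, pi=0.99))
            f0 = fit_markers_bayesB(y_noise, X, spec=spec)
            y_qtl = _series(X[:, 0] * 1.0 + rng.standard_normal(n))
            f1 = fit_markers_bayesB(y_qtl, X, spec=spec)
            if np.abs(f0.beta_add).max() < 0.1 * np.abs(f1.beta_add).max():
                smaller += 1
        assert smaller >= 8

    def test_same_seed_identical_posterior(self):
        rng = np.random.default_rng(8)
        X = rng.choice([-1.0, 1.0], size=(60, 80))
        y = _series(rng.standard_normal(60))
        spec = ModelSpec("BayesB", hyperparameters=MCMC_SMALL)
        f1 = fit_markers_bayesB(y, X, spec=spec)
        f2 = fit_markers_bayesB(y, X, spec=spec)
        assert np.array_equal(f1.beta_add, f2.beta_add)

    def test_chain_shorter_than_burnin_rejected(self):
        X = np.zeros((10, 3))
        y = _series(np.arange(10.0))
        with pytest.raises(ValueError, match="burn-in"):
            fit_markers_bayesB(y, X, spec=ModelSpec(
                "BayesB", hyperparameters={"n_iter": 100, "burn_in": 200}))


class TestBayesianLasso:
    def test_zero_phenotype_gives_zero_fit(self):
        rng = np.random.default_rng(9)
        X = rng.choice([-1.0, 1.0], size=(50, 40))
        y = _series(np.zeros(50))
        fit = fit_markers_blasso(
            y, X, spec=ModelSpec("BayesianLasso", hyperparameters=MCMC_SMALL))
        assert abs(fit.mu) < 0.05
        assert np.abs(fit.beta_add).max() < 0.05

    def test_dense_trait_matches_gblup(self, small_sim):
        """Under a dense polygenic architecture the Lasso posterior-mean
        predictions nearly coincide with GBLUP."""
        from hybridgs.synthetic_data import (TraitArchitecture,
                                             assign_trait_architecture,
                                             simulate_phenotypes)
        G = small_sim.G_f1
        arch = TraitArchitecture("dense", n_qtl=400, sigma2_A=0.7,
                                 sigma2_D=0.0, sigma2_e=0.3)
        truth = assign_trait_architecture(G, arch, seed=10)
        y = simulate_phenotypes(truth, 0.3, seed=11)
        X = G.calls.astype(float)
        fit_bl = fit_markers_blasso(
            y, X, spec=ModelSpec("BayesianLasso", hyperparameters=MCMC_SMALL))
        fit_g = fit_gblup(y, additive_kinship(G))
        r = np.corrcoef(fit_bl.fitted_values, fit_g.fitted_values)[0, 1]
        assert r > 0.95

    def test_same_seed_identical_posterior(self):
        rng = np.random.default_rng(10)
        X = rng.choice([-1.0, 1.0], size=(40, 30))
        y = _series(rng.standard_normal(40))
        spec = ModelSpec("BayesianLasso", hyperparameters=MCMC_SMALL)
        f1 = fit_markers_blasso(y, X, spec=spec)
        f2 = fit_markers_blasso(y, X, spec=spec)
        assert np.array_equal(f1.beta_add, f2.beta_add)


class TestDominanceTerm:
    def test_never_decreases_in_sample_fit(self, small_sim):
        """Adding the dominance kinship never lowers training R2."""
        G = small_sim.G_f1
        A = additive_kinship(G)
        D = dominance_kinship(G)
        rng = np.random.default_rng(11)
        for rep in range(3):
            y = pd.Series(rng.standard_normal(G.n_individuals),
                          index=G.individuals, name="t")
            fA = fit_gblup(y, A)
            fAD = fit_gblup(y, A, D)
            r2 = lambda f: np.corrcoef(f.fitted_values, y)[0, 1] ** 2
            assert r2(fAD) >= r2(fA) - 1e-6

    def test_marker_dominance_design_improves_het_trait(self, small_sim):
        """A trait driven by heterozygosity alone is captured by the
        additive+dominant marker model, not the additive one."""
        G = small_sim.G_f1
        H = heterozygosity_design(G)
        rng = np.random.default_rng(12)
        d = rng.standard_normal(G.n_markers) * (rng.random(G.n_markers) < 0.05)
        g = H @ d
        g = (g - g.mean()) / g.std()
        y = pd.Series(g + rng.normal(0, 0.5, len(g)), index=G.individuals,
                      name="t")
        X = G.calls.astype(float)
        spec_a = ModelSpec("BayesB", "additive", MCMC_SMALL)
        spec_ad = ModelSpec("BayesB", "additive_dominant", MCMC_SMALL)
        fa = fit_markers_bayesB(y, X, spec=spec_a)
        fad = fit_markers_bayesB(y, X, heterozygosity_design(G, center=True),
                                 spec=spec_ad)
        ra = np.corrcoef(fa.fitted_values, y)[0, 1]
        rad = np.corrcoef(fad.fitted_values, y)[0, 1]
        assert rad > ra


class TestRKHS:
    def test_kernel_diagonal_is_one(self, inbred_G):
        K = gaussian_kernel(inbred_G.calls.astype(float),
                            inbred_G.individuals)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_large_bandwidth_predicts_mu_for_held_out(self, inbred_G):
        rng = np.random.default_rng(13)
        y = pd.Series(5.0 + rng.standard_normal(30),
                      index=inbred_G.individuals[:30], name="t")
        fit = fit_rkhs(y, inbred_G, bandwidth=1e6)
        pred = predict_gblup(fit, fit.kernel,
                             test_ids=inbred_G.individuals[30:])
        assert np.abs(pred - fit.mu).max() < 1e-3

    def test_degenerate_genotypes_raise(self):
        calls = np.ones((5, 10))
        with pytest.raises(ValueError, match="degenerate"):
            gaussian_kernel(calls, [f"i{k}" for k in range(5)])

    def test_additive_dominant_spec_rejected(self):
        with pytest.raises(ValueError, match="dominance"):
            ModelSpec("RKHS", "additive_dominant")
        with pytest.raises(ValueError, match="dominance"):
            ModelSpec("TreeEnsemble", "additive_dominant")


class TestTreeEnsemble:
    def test_constant_y_gives_constant_predictions(self):
        rng = np.random.default_rng(14)
        X = rng.choice([-1.0, 1.0], size=(40, 20))
        y = _series(np.full(40, 2.5))
        fit = fit_tree_ensemble(y, X, spec=ModelSpec(
            "TreeEnsemble", hyperparameters={"n_trees": 50}))
        assert np.allclose(fit.model.predict(X), 2.5)

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(15)
        X = rng.choice([-1.0, 1.0], size=(50, 30))
        y = _series(rng.standard_normal(50))
        spec = ModelSpec("TreeEnsemble",
                         hyperparameters={"n_trees": 50, "seed": 4})
        f1 = fit_tree_ensemble(y, X, spec=spec)
        f2 = fit_tree_ensemble(y, X, spec=spec)
        assert np.array_equal(f1.model.predict(X), f2.model.predict(X))

    def test_captures_pure_dominance_signal(self):
        """Phenotype depending on heterozygosity only: the forest beats
        an additive linear fit in-sample."""
        rng = np.random.default_rng(16)
        n, m = 200, 60
        X = rng.choice([-1.0, 0.0, 1.0], size=(n, m), p=[0.35, 0.3, 0.35])
        y_raw = (X[:, 0] == 0).astype(float) + rng.normal(0, 0.3, n)
        y = _series(y_raw)
        fit_rf = fit_tree_ensemble(y, X, spec=ModelSpec(
            "TreeEnsemble", hyperparameters={"n_trees": 200}))
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(
            np.hstack([np.ones((n, 1)), Xc[:, :1]]), y_raw, rcond=None)
        lin_fit = beta[0] + Xc[:, 0] * beta[1]
        r_rf = np.corrcoef(fit_rf.fitted_values, y_raw)[0, 1]
        r_lin = abs(np.corrcoef(lin_fit, y_raw)[0, 1])
        assert r_rf > r_lin
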