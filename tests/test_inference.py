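import numpy as np
import pytest
from scipy.stats import multivariate_normal

from spingarch import (
    ModelParams,
    build_lattice,
    log_latent_density,
    log_likelihood_counts,
    log_posterior,
    log_prior,
    simulate,
)
from spingarch.inference import (
    ChainConfig,
    PriorSpec,
    _greedy_coloring,
    reconstruct_intensity,
    run_mcmc,
)
from spingarch.model import CountPanel, LatentPath
from spingarch.synthetic import generate_city_lattice

from conftest import random_small_lattice, random_valid_carspec


def _params(n, T, **kw):
    defaults = dict(eta=0.2, kappa=0.1, sigma=0.4, sigma_eps=0.5, zeta=0.5,
                    alpha=np.zeros((n, T)))
    defaults.update(kw)
    return ModelParams(**defaults)


class TestLogPrior:
    def test_constraint_violation(self):
        theta = _params(1, 1)
        theta.eta, theta.kappa = 0.6, 0.5  # bypass validation deliberately
        assert log_prior(theta, PriorSpec()) == -np.inf

    def test_flat_beta_half_cauchy_closed_form(self):
        priors = PriorSpec(eta_beta=(1, 1), kappa_beta=(1, 1),
                           sigma_cauchy_scale=1.0, sigma_eps_cauchy_scale=1.0)
        theta = _params(1, 1, eta=0.3, kappa=0.3, sigma=0.0, sigma_eps=0.0)
        # triangle-truncated uniform normalizes to 2; each half-Cauchy at 0 is 2/pi
        expected = np.log(2.0) + 2 * np.log(2.0 / np.pi)
        assert log_prior(theta, priors) == pytest.approx(expected, abs=1e-8)

    def test_symmetry_in_eta_kappa(self):
        priors = PriorSpec(eta_beta=(2, 3), kappa_beta=(2, 3))
        a = log_prior(_params(1, 1, eta=0.2, kappa=0.55), priors)
        b = log_prior(_params(1, 1, eta=0.55, kappa=0.2), priors)
        assert a == pytest.approx(b, abs=1e-10)


class TestLogLatentDensity:
    def test_zeta_zero_reduces_to_diagonal(self):
        rng = np.random.default_rng(0)
        lat = generate_city_lattice(2, 2)
        n, T = 4, 3
        X = rng.normal(size=(n, T))
        eps = rng.normal(size=(n, T))
        alpha = rng.normal(size=(n, T))
        theta = _params(n, T, zeta=0.0, sigma=0.7, sigma_eps=0.3, alpha=alpha)
        latent = LatentPath(X=X, eps=eps, U=X + eps)
        got = log_latent_density(latent, alpha, theta, lat)
        from scipy.stats import norm

        expected = norm.logpdf(X, alpha, 0.7).sum() + norm.logpdf(eps, 0, 0.3).sum()
        assert got == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            lat = random_small_lattice(rng, n_max=4)
            spec = random_valid_carspec(rng, lat)
            n, T = lat.n, 2
            X = rng.normal(size=(n, T))
            eps = rng.normal(size=(n, T))
            alpha = rng.normal(size=(n, T))
            theta = _params(n, T, zeta=spec.zeta, sigma=np.sqrt(spec.sigma2),
                            sigma_eps=0.6, alpha=alpha)
            latent = LatentPath(X=X, eps=eps, U=X + eps)
            got = log_latent_density(latent, alpha, theta, lat)
            cov = np.linalg.inv(np.eye(n) - spec.zeta * lat.N_scaled) * spec.sigma2
            expected = sum(
                multivariate_normal.logpdf(X[:, t], alpha[:, t], cov) for t in range(T)
            )
            expected += sum(
                multivariate_normal.logpdf(eps[:, t], np.zeros(n),
                                           0.36 * np.eye(n)) for t in range(T)
            )
            assert got == pytest.approx(expected, abs=1e-8)

    def test_translation_invariance_of_car_term(self):
        rng = np.random.default_rng(2)
        lat = generate_city_lattice(2, 2)
        X = rng.normal(size=(4, 3))
        alpha = rng.normal(size=(4, 3))
        eps = np.zeros((4, 3))
        theta = _params(4, 3, sigma_eps=1.0)
        l1 = log_latent_density(LatentPath(X, eps, X), alpha, theta, lat)
        l2 = log_latent_density(LatentPath(X + 5.0, eps, X + 5.0), alpha + 5.0, theta, lat)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_zero_sigma_eps_with_nonzero_eps(self):
        lat = generate_city_lattice(2, 2)
        X = np.zeros((4, 2))
        eps = np.ones((4, 2))
        theta = _params(4, 2, sigma_eps=0.0)
        assert log_latent_density(LatentPath(X, eps, X + eps), np.zeros((4, 2)),
                                  theta, lat) == -np.inf


class TestLogLikelihood:
    def test_closed_form(self):
        got = log_likelihood_counts(np.array([[2]]), np.array([[1.0]]))
        assert got == pytest.approx(-1.0 - np.log(2.0), abs=1e-12)

    def test_maximized_at_lambda_equals_y(self):
        y = np.array([[4]])
        at_y = log_likelihood_counts(y, np.array([[4.0]]))
        for lam in (2.0, 3.5, 5.0, 8.0):
            assert log_likelihood_counts(y, np.array([[lam]])) < at_y

    def test_additivity(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(2.0, size=(4, 5))
        lam = rng.uniform(0.5, 3.0, size=(4, 5))
        total = log_likelihood_counts(Y, lam)
        cells = sum(
            log_likelihood_counts(Y[i: i + 1, j: j + 1], lam[i: i + 1, j: j + 1])
            for i in range(4) for j in range(5)
        )
        assert total == pytest.approx(cells, abs=1e-9)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood_counts(np.array([[1]]), np.array([[0.0]]))


class TestReconstructIntensity:
    def test_matches_manual_recursion(self):
        rng = np.random.default_rng(4)
        n, T = 3, 12
        U = rng.normal(size=(n, T))
        Y = rng.poisson(1.5, size=(n, T))
        lam0 = rng.uniform(0.5, 2.0, n)
        eta, kappa = 0.3, 0.4
        lam = reconstruct_intensity(U, Y, eta, kappa, lam0)
        manual = np.empty((n, T))
        manual[:, 0] = np.exp(U[:, 0]) + kappa * lam0
        for t in range(1, T):
            manual[:, t] = np.exp(U[:, t]) + eta * Y[:, t - 1] + kappa * manual[:, t - 1]
        assert np.allclose(lam, manual, atol=1e-12)

    def test_kappa_zero(self):
        U = np.zeros((2, 3))
        Y = np.array([[1, 2, 3], [0, 0, 0]])
        lam = reconstruct_intensity(U, Y, 0.5, 0.0, np.ones(2))
        assert np.allclose(lam[:, 1], 1.0 + 0.5 * Y[:, 0])


class TestAssemblyIdentity:
    def test_log_posterior_composition(self):
        rng = np.random.default_rng(5)
        lat = generate_city_lattice(2, 3)
        n, T = 6, 4
        theta = _params(n, T, alpha=rng.normal(size=(n, T)))
        counts, intensity, latent = simulate(theta, lat, T, seed=8)
        priors = PriorSpec()
        lp = log_posterior(counts, latent, theta.alpha, theta, lat, priors,
                           lam0=intensity.lam0)
        lam = reconstruct_intensity(latent.U, counts.Y, theta.eta, theta.kappa,
                                    intensity.lam0)
        manual = (
            log_prior(theta, priors)
            + log_latent_density(latent, theta.alpha, theta, lat)
            + log_likelihood_counts(counts.Y, lam)
        )
        assert lp == pytest.approx(manual, abs=1e-10)
        assert np.allclose(lam, intensity.lam, atol=1e-10)


class TestColoring:
    def test_grid_is_two_colorable(self, grid6):
        colors = _greedy_coloring(grid6.N_raw)
        assert len(colors) == 2
        for cls in colors:
            sub = grid6.N_raw[np.ix_(cls, cls)]
            assert not sub.any()

    def test_covers_all_sites(self):
        rng = np.random.default_rng(6)
        lat = random_small_lattice(rng)
        colors = _greedy_coloring(lat.N_raw)
        assert sorted(np.concatenate(colors)) == list(range(lat.n))
        for cls in colors:
            assert not lat.N_raw[np.ix_(cls, cls)].any()


class TestChainConfig:
    def test_retained_count_default(self):
        cfg = ChainConfig()
        assert cfg.retained_per_chain == 600

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)
        with pytest.raises(ValueError):
            ChainConfig(fix_params={"bogus": 1.0})


class TestRunMCMC:
    def test_degenerate_sigma_eps_recovery(self):
        lat = build_lattice([], ["a"])
        p = ModelParams(eta=0, kappa=0, sigma=0, sigma_eps=0.8, zeta=0.0,
                        alpha=np.zeros((1, 200)))
        Y, _, _ = simulate(p, lat, 200, seed=3)
        cfg = ChainConfig(n_chains=2, n_iter=4000, burn_in=1000, thin=5, seed=0,
                          fix_params={"eta": 0.0, "kappa": 0.0, "sigma": 0.0},
                          zeta_fixed=0.0)
        d = run_mcmc(Y, np.zeros((1, 200)), lat, PriorSpec(), cfg)
        assert abs(d.posterior_mean("sigma_eps") - 0.8) / 0.8 < 0.2

    def test_determinism(self):
        lat = generate_city_lattice(3, 3)
        p = _params(9, 15)
        Y, _, _ = simulate(p, lat, 15, seed=2)
        cfg = ChainConfig(n_chains=2, n_iter=300, burn_in=100, thin=4, seed=7,
                          zeta_fixed=0.5)
        d1 = run_mcmc(Y, p.alpha, lat, PriorSpec(), cfg)
        d2 = run_mcmc(Y, p.alpha, lat, PriorSpec(), cfg)
        assert np.array_equal(d1.draws, d2.draws)
        assert np.array_equal(d1.logpost, d2.logpost)

    def test_retained_count_and_constraints(self):
        lat = generate_city_lattice(2, 2)
        p = _params(4, 10)
        Y, _, _ = simulate(p, lat, 10, seed=5)
        cfg = ChainConfig(n_chains=3, n_iter=500, burn_in=200, thin=10, seed=1,
                          zeta_fixed=0.5)
        d = run_mcmc(Y, p.alpha, lat, PriorSpec(), cfg)
        assert len(d.chain_id) == 3 * cfg.retained_per_chain
        eta, kappa = d.column("eta"), d.column("kappa")
        assert np.all(eta + kappa < 1)
        assert np.all(eta > 0) and np.all(kappa > 0)
        assert np.all(d.column("tau") > 0)
        assert np.all(d.column("sigma_eps") > 0)
        assert np.all(np.isfinite(d.logpost))

    def test_posterior_sd_shrinks_with_T(self):
        lat = generate_city_lattice(3, 3)
        sds = {T: [] for T in (15, 60)}
        for rep in range(3):
            for T in (15, 60):
                p = _params(9, T, eta=0.3, kappa=0.1, sigma=0.4, sigma_eps=0.6,
                            zeta=0.9, alpha=np.zeros((9, T)))
                Y, _, _ = simulate(p, lat, T, seed=100 + rep)
                cfg = ChainConfig(n_chains=1, n_iter=1200, burn_in=400, thin=4,
                                  seed=rep, zeta_fixed=0.9)
                d = run_mcmc(Y, p.alpha, lat, PriorSpec(), cfg)
                sds[T].append(np.std(d.column("eta")))
        assert np.mean(sds[60]) < np.mean(sds[15])

    def test_shape_mismatch_rejected(self):
        lat = generate_city_lattice(2, 2)
        with pytest.raises(ValueError, match="match"):
            run_mcmc(np.zeros((4, 5), dtype=int), np.zeros((4, 6)), lat)

    def test_dataframe_round_trip(self):
        lat = generate_city_lattice(2, 2)
        p = _params(4, 8)
        Y, _, _ = simulate(p, lat, 8, seed=9)
        cfg = ChainConfig(n_chains=2, n_iter=200, burn_in=100, thin=5, seed=3,
                          zeta_fixed=0.5)
        d = run_mcmc(Y, p.alpha, lat, PriorSpec(), cfg)
        df = d.to_dataframe()
        assert list(df.columns) == ["chain", "iter", "eta", "kappa", "tau",
                                    "sigma_eps", "logpost"]
        from spingarch.inference import PosteriorDraws

        d2 = PosteriorDraws.from_dataframe(df)
        assert np.allclose(d2.draws, d.draws)
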