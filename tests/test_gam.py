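import warnings

import numpy as np
import pytest

from spingarch import (
    CovariatePanel,
    GAMConfig,
    bspline_basis,
    fit_alpha_gam,
    gcv_score,
    predict_alpha,
    tensor_row_kronecker,
)


class TestBsplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-3, 7, 200)
        for k, deg in [(4, 3), (10, 3), (6, 2), (12, 1)]:
            b = bspline_basis(x, k, deg)
            assert np.allclose(b.B.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(b.B >= 0)
            assert b.num_basis == k

    def test_degree_zero_single_interval(self):
        b = bspline_basis(np.linspace(0, 1, 20), 1, 0)
        assert b.B.shape == (20, 1)
        assert np.allclose(b.B, 1.0)

    def test_cubic_contains_linear(self):
        # oracle: direct least-squares on the basis reproduces a linear function
        x = np.linspace(0, 1, 100)
        y = 2 * x + 1
        b = bspline_basis(x, 10, 3)
        coef, *_ = np.linalg.lstsq(b.B, y, rcond=None)
        assert np.max(np.abs(b.B @ coef - y)) < 1e-8

    def test_too_few_basis_rejected(self):
        with pytest.raises(ValueError, match="num_basis"):
            bspline_basis(np.linspace(0, 1, 10), 3, 3)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bspline_basis(np.ones(10), 8, 3)

    def test_evaluate_clamps_with_warning(self):
        b = bspline_basis(np.linspace(0, 1, 50), 8, 3)
        with pytest.warns(UserWarning, match="clamping"):
            B_out = b.evaluate(np.array([-1.0, 2.0]))
        B_edge = b.evaluate(np.array([0.0, 1.0]))
        assert np.allclose(B_out, B_edge)


class TestTensorRowKronecker:
    def test_all_ones(self):
        out = tensor_row_kronecker(np.ones((5, 1)), np.ones((5, 1)))
        assert np.allclose(out, 1.0)

    def test_forced_arithmetic(self):
        out = tensor_row_kronecker(np.array([[1.0, 2.0]]), np.array([[3.0, 4.0, 5.0]]))
        assert np.allclose(out, [[3, 4, 5, 6, 8, 10]])

    def test_shape_contract(self):
        rng = np.random.default_rng(1)
        B1, B2 = rng.normal(size=(7, 4)), rng.normal(size=(7, 6))
        assert tensor_row_kronecker(B1, B2).shape == (7, 24)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        B1, B2 = rng.normal(size=(9, 3)), rng.normal(size=(9, 5))
        out = tensor_row_kronecker(B1, B2)
        brute = np.vstack([np.kron(B1[i], B2[i]) for i in range(9)])
        assert np.array_equal(out, brute)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="row-count"):
            tensor_row_kronecker(np.ones((3, 2)), np.ones((4, 2)))


class TestGCV:
    def test_zero_rss(self):
        assert gcv_score(0.0, 100, 5.0) == 0.0

    def test_forced_arithmetic(self):
        assert gcv_score(50.0, 100, 0.0) == pytest.approx(0.5)

    def test_monotone_in_rss(self):
        vals = [gcv_score(r, 50, 3.0) for r in (1.0, 2.0, 5.0)]
        assert vals == sorted(vals)

    def test_edf_bound(self):
        with pytest.raises(ValueError):
            gcv_score(1.0, 10, 10.0)


class TestCovariatePanel:
    def test_broadcast_spatial_temporal(self):
        sp = CovariatePanel("pob", np.arange(3, dtype=float), "spatial")
        tm = CovariatePanel("temp", np.arange(4, dtype=float), "temporal")
        assert np.allclose(sp.to_panel(3, 4)[:, 2], [0, 1, 2])
        assert np.allclose(tm.to_panel(3, 4)[1], [0, 1, 2, 3])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            CovariatePanel("bad", np.array([1.0, np.nan]), "spatial")


class TestFitAlphaGam:
    def test_noise_free_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(15, 25))
        resp = np.exp(0.5 + 1.3 * x)
        fit = fit_alpha_gam(resp, [CovariatePanel("c", x, "spatiotemporal")])
        assert np.max(np.abs(fit.fitted_alpha - (0.5 + 1.3 * x))) < 1e-3

    def test_sinusoid_beats_linear(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(20, 30))
        mu = np.exp(0.3 + np.sin(2 * np.pi * x))
        y = rng.poisson(5 * mu) / 5.0 + 0.01
        cov = [CovariatePanel("s", x, "spatiotemporal")]
        fs = fit_alpha_gam(y, cov, GAMConfig())
        fl = fit_alpha_gam(y, cov, GAMConfig(term_mode="linear"))
        truth = np.log(mu)
        rmse = lambda f: np.sqrt(np.mean((f.fitted_alpha - truth) ** 2))
        assert rmse(fs) < rmse(fl)

    def test_pure_noise_term_shrinks(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(20, 30))
        junk = rng.uniform(0, 1, size=(20, 30))
        mu = np.exp(0.3 + np.sin(2 * np.pi * x))
        y = rng.poisson(5 * mu) / 5.0 + 0.01
        fit = fit_alpha_gam(
            y,
            [CovariatePanel("s", x, "spatiotemporal"),
             CovariatePanel("junk", junk, "spatiotemporal")],
        )
        assert fit.edf["junk"] <= 2.0

    def test_gcv_never_worse_than_candidates(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=(10, 20))
        y = rng.poisson(np.exp(1 + x)) + 0.01
        fit = fit_alpha_gam(y.astype(float), [CovariatePanel("c", x, "spatiotemporal")])
        assert fit.gcv <= np.min(fit.gcv_candidates) + 1e-12

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, size=(12, 18))
        y = rng.poisson(np.exp(0.5 + np.sin(3 * x))).astype(float) + 0.01
        f1 = fit_alpha_gam(y, [CovariatePanel("c", x, "spatiotemporal")])
        f2 = fit_alpha_gam(y, [CovariatePanel("c", 100.0 * x - 7.0, "spatiotemporal")])
        assert np.max(np.abs(f1.fitted_alpha - f2.fitted_alpha)) < 1e-6

    def test_nonfinite_covariate_rejected(self):
        y = np.ones((3, 4))
        bad = np.ones((3, 4))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_alpha_gam(y, [CovariatePanel("b", np.log(bad), "spatiotemporal")])

    def test_no_covariates_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_alpha_gam(np.ones((3, 4)), [])

    def test_term_selection_drops_junk(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, size=(20, 40))
        junk = rng.uniform(0, 1, size=(20, 40))
        y = rng.poisson(np.exp(1.0 + 2.0 * x)).astype(float) + 0.01
        fit = fit_alpha_gam(
            y,
            [CovariatePanel("real", x, "spatiotemporal"),
             CovariatePanel("junk", junk, "spatiotemporal")],
            GAMConfig(select_terms=True, signif_threshold=1e-4),
        )
        assert "real" in fit.term_names()


class TestPredictAlpha:
    def _fit(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, size=(10, 15))
        y = np.exp(0.5 + x)
        cov = CovariatePanel("c", x, "spatiotemporal")
        return fit_alpha_gam(y, [cov]), cov, x

    def test_reproduces_training_fit(self):
        fit, cov, _ = self._fit()
        pred = predict_alpha(fit, [cov])
        assert np.allclose(pred, fit.fitted_alpha, atol=1e-10)

    def test_unknown_covariate_rejected(self):
        fit, _, x = self._fit()
        with pytest.raises(KeyError):
            predict_alpha(fit, [CovariatePanel("other", x, "spatiotemporal")])

    def test_extrapolation_clamped_with_warning(self):
        fit, _, x = self._fit()
        far = CovariatePanel("c", x + 100.0, "spatiotemporal")
        with pytest.warns(UserWarning, match="clamping"):
            pred_far = predict_alpha(fit, [far])
        edge = CovariatePanel("c", np.full_like(x, x.max()), "spatiotemporal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred_edge = predict_alpha(fit, [edge])
        assert np.allclose(pred_far, pred_edge)
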