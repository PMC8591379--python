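"""PGLS estimation: GLS core, REML profiling, AICc selection, Wald tests."""

import numpy as np
import pytest
from scipy import linalg, stats

import allomvox as av
from allomvox.covariance import CovarianceSpec, bm_vcv
from allomvox.pgls import PGLS, aicc, gls_fit, select_model
from allomvox.simulate import simulate_bm_on_tree, simulate_tree


def whitening_oracle(y, X, V):
    """Brute-force GLS via explicit inverse (independent of the implementation)."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


@pytest.fixture
def design(rng):
    n = 40
    x = rng.uniform(0, 5, n)
    X = np.column_stack([np.ones(n), x])
    return X


class TestGLSCore:
    def test_identity_covariance_equals_ols(self, design, rng):
        y = 1.0 + 2.0 * design[:, 1] + rng.normal(size=len(design))
        core = gls_fit(y, design, np.eye(len(design)))
        ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(core.params, ols, atol=1e-10)
        # OLS standard errors too
        r = y - design @ ols
        s2 = r @ r / (len(y) - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(design.T @ design)))
        np.testing.assert_allclose(core.bse, se, atol=1e-10)

    def test_exact_linear_data_interpolates(self, random_tree):
        t = random_tree(10, 1)
        x = np.linspace(0, 3, 10)
        y = 2.0 + 3.0 * x
        X = np.column_stack([np.ones(10), x])
        core = gls_fit(y, X, bm_vcv(t).values)
        np.testing.assert_allclose(core.params, [2.0, 3.0], atol=1e-8)
        np.testing.assert_allclose(core.resid, 0.0, atol=1e-8)

    def test_matches_whitening_oracle_on_tree(self, rng):
        t = simulate_tree(5, 3)
        V = bm_vcv(t).values
        x = rng.uniform(0, 4, 5)
        X = np.column_stack([np.ones(5), x])
        y = 1.0 - 0.5 * x + rng.multivariate_normal(np.zeros(5), 0.3 * V)
        core = gls_fit(y, X, V)
        np.testing.assert_allclose(core.params, whitening_oracle(y, X, V),
                                   atol=1e-8)

    def test_residuals_on_response_scale(self, design, rng):
        t = simulate_tree(len(design), 4)
        V = bm_vcv(t).values
        y = rng.normal(size=len(design))
        core = gls_fit(y, design, V)
        np.testing.assert_allclose(core.resid, y - design @ core.params,
                                   atol=1e-12)

    def test_non_psd_covariance_raises(self, design, rng):
        y = rng.normal(size=len(design))
        V = -np.eye(len(design))
        with pytest.raises(linalg.LinAlgError):
            gls_fit(y, design, V)

    def test_singular_design_raises(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="singular"):
            gls_fit(rng.normal(size=n), X, np.eye(n))


class TestAICc:
    def test_correction_term_closed_form(self):
        # k=4, n=164: correction 2*4*5/159 added to AIC
        llf = -100.0
        assert aicc(llf, 164, 4) == pytest.approx(-2 * llf + 8 + 40 / 159)

    def test_limits_to_aic_for_large_n(self):
        llf = -50.0
        assert abs(aicc(llf, 10 ** 8, 3) - (-2 * llf + 6)) < 1e-6

    def test_monotone_penalty_prefers_smaller_k(self):
        assert aicc(-10.0, 50, 3) < aicc(-10.0, 50, 4)

    def test_small_n_raises(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 4)


class TestProfile:
    def _lambda_data(self, n, lam, seed):
        tree = simulate_tree(n, seed)
        rng = np.random.default_rng(seed + 1000)
        x = rng.uniform(0.5, 7.5, n)
        if lam == 0.0:
            noise = rng.normal(size=n) * 0.2
        else:
            noise = simulate_bm_on_tree(tree, 0.04, seed + 2000,
                                        lambda_=lam).loc[tree.tips].to_numpy()
        y = 2.7 - 0.37 * x + noise
        X = np.column_stack([np.ones(n), x])
        return tree, y, X

    def test_recovers_strong_phylogenetic_signal(self):
        tree, y, X = self._lambda_data(164, 1.0, seed=5)
        res = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM_lambda")).fit()
        assert res.phylo_parameter > 0.8

    def test_recovers_absent_signal(self):
        tree, y, X = self._lambda_data(164, 0.0, seed=6)
        res = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM_lambda")).fit()
        assert res.phylo_parameter < 0.2

    def test_optimum_at_least_as_good_as_endpoints(self):
        tree, y, X = self._lambda_data(80, 0.6, seed=7)
        model = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM_lambda"))
        res = model.fit()
        for lam in (0.0, 1.0):
            endpoint = gls_fit(y, X, model._vcv(lam), "REML")
            assert res.llf_reml >= endpoint.llf_reml - 1e-9

    def test_bm_spec_equals_plain_gls(self):
        tree, y, X = self._lambda_data(30, 1.0, seed=8)
        res = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM")).fit()
        core = gls_fit(y, X, bm_vcv(tree).values, "REML")
        np.testing.assert_allclose(res.params, core.params, atol=1e-12)
        assert res.llf_reml == pytest.approx(core.llf_reml, abs=1e-12)

    def test_slope_invariant_to_log_base(self):
        # regressing ln(y) on ln(x) vs log10(y) on log10(x): same slope
        # (compared at a common covariance; profiling adds only its own
        # optimizer tolerance, checked separately)
        tree, y, X = self._lambda_data(60, 0.8, seed=9)
        ln10 = np.log(10.0)
        X_nat = X.copy()
        X_nat[:, 1] = X[:, 1] * ln10
        res10 = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM")).fit()
        resln = PGLS(y * ln10, X_nat, tree=tree,
                     covariance=CovarianceSpec("BM")).fit()
        assert res10.params[1] == pytest.approx(resln.params[1], abs=1e-10)
        lam10 = PGLS(y, X, tree=tree,
                     covariance=CovarianceSpec("BM_lambda")).fit()
        lamln = PGLS(y * ln10, X_nat, tree=tree,
                     covariance=CovarianceSpec("BM_lambda")).fit()
        assert lam10.params[1] == pytest.approx(lamln.params[1], abs=1e-6)


class TestSelection:
    def _fits(self, seed=11):
        tree = simulate_tree(50, seed)
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 5, 50)
        y = (1 - 0.4 * x
             + simulate_bm_on_tree(tree, 0.05, seed + 1).loc[tree.tips].to_numpy())
        X = np.column_stack([np.ones(50), x])
        specs = [CovarianceSpec("BM"), CovarianceSpec("BM_lambda"),
                 CovarianceSpec("OU_fixed", parameter=1.0)]
        return [PGLS(y, X, tree=tree, covariance=s).fit() for s in specs]

    def test_argmin_aicc_selected(self):
        fits = self._fits()
        comp = select_model(fits)
        assert comp.best.aicc == min(f.aicc for f in fits)

    def test_exact_tie_prefers_fewer_parameters(self):
        fits = self._fits()
        # force an exact AICc tie between BM (k=3) and BM+lambda (k=4)
        fits[1].aicc = fits[0].aicc
        comp = select_model(fits)
        assert comp.best is fits[0]

    def test_mixed_datasets_rejected(self):
        f1 = self._fits(seed=11)
        f2 = self._fits(seed=12)
        with pytest.raises(ValueError):
            select_model([f1[0], f2[0]])


class TestWald:
    def test_chi_square_normal_equivalence(self):
        # a |t|-like ratio of 1.96 corresponds to p ~= 0.05 with 1 df
        assert stats.chi2.sf(1.96 ** 2, 1) == pytest.approx(0.05, abs=5e-4)

    def test_statistic_matches_ml_refit_coefficients(self, random_tree, rng):
        t = random_tree(20, 13)
        x = rng.uniform(0, 1, 20)
        y = 1.0 + 0.5 * x + rng.normal(size=20) * 0.3
        X = np.column_stack([np.ones(20), x])
        res = PGLS(y, X, tree=t, covariance=CovarianceSpec("BM")).fit()
        ml = res._core_ml
        for (chi2, p), b, se in zip(res.wald_anova(), ml.params, ml.bse):
            assert chi2 == pytest.approx((b / se) ** 2, rel=1e-12)
            assert p == pytest.approx(float(stats.chi2.sf(chi2, 1)), rel=1e-12)

    def test_null_slope_type_one_error(self):
        # 500 ML refit Wald tests on null-slope data; rejection rate near
        # 0.05 (the chi-square reference is asymptotic, so study-scale n)
        n = 150
        tree = simulate_tree(n, 17)
        V = bm_vcv(tree).values
        rng = np.random.default_rng(17)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        rejections = 0
        for _ in range(500):
            x = rng.uniform(0, 5, n)
            y = 1.0 + L @ rng.normal(size=n) * 0.3
            X = np.column_stack([np.ones(n), x])
            core_ml = gls_fit(y, X, V, "ML")
            chi2 = (core_ml.params[1] / core_ml.bse[1]) ** 2
            rejections += stats.chi2.sf(chi2, 1) <= 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_summary_renders(self):
        tree = simulate_tree(20, 19)
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 5, 20)
        y = 1 - 0.3 * x + rng.normal(size=20) * 0.1
        X = np.column_stack([np.ones(20), x])
        res = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM_lambda"),
                   exog_names=["intercept", "log_body_mass"]).fit()
        text = res.summary()
        assert "AICc" in text and "log_body_mass" in text and "Wald" in text
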