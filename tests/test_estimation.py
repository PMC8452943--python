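import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit, logsumexp

import cdmkit as ck


class TestClassLikelihoods:
    def test_single_item_reads_off_irf(self):
        q = ck.QMatrix(entries=np.array([[1]]))
        irf = ck.ItemResponseFunction(model="gdina", q=q, probs=[[0.2, 0.9]])
        lik = ck.class_likelihoods(irf, np.array([[1], [0]]))
        assert lik[0] == pytest.approx([0.2, 0.9])
        assert lik[1] == pytest.approx([0.8, 0.1])

    def test_certain_class_has_unit_likelihood(self):
        q = ck.QMatrix(entries=np.array([[1], [1]]))
        irf = ck.ItemResponseFunction(model="gdina", q=q, probs=[[0.0, 1.0], [0.0, 1.0]])
        lik = ck.class_likelihoods(irf, np.array([[1, 1]]))
        assert lik[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_product(self, q_small, rng):
        probs = [rng.uniform(0.1, 0.9, 2), rng.uniform(0.1, 0.9, 2), rng.uniform(0.1, 0.9, 4)]
        irf = ck.ItemResponseFunction(model="gdina", q=q_small, probs=probs)
        space = ck.enumerate_patterns(2)
        X = rng.integers(0, 2, size=(5, 3))
        lik = ck.class_likelihoods(irf, X, space)
        P = irf.expand(space)
        for i in range(5):
            for c in range(4):
                expected = np.prod([P[j, c] if X[i, j] else 1 - P[j, c] for j in range(3)])
                assert lik[i, c] == pytest.approx(expected, rel=1e-8)


def marginal_loglik(X, Q, probs, pi):
    """Independent re-implementation of the mixture log-likelihood."""
    space = ck.enumerate_patterns(Q.K)
    irf = ck.ItemResponseFunction(model="gdina", q=Q, probs=probs)
    P = np.clip(irf.expand(space), 1e-12, 1 - 1e-12)
    ll = X @ np.log(P) + (1 - X) @ np.log(1 - P) + np.log(np.maximum(pi, 1e-300))
    return float(logsumexp(ll, axis=1).sum())


class TestEMAgainstOracles:
    def test_single_item_marginal_mle_is_binomial(self, rng):
        """With one single-attribute item the marginal model collapses to a
        Bernoulli with mean pi*(1-s) + (1-pi)*g: the achievable maximum of
        the marginal likelihood is the binomial one at the sample mean."""
        X = (rng.random((50, 1)) < 0.62).astype(int)
        q = ck.QMatrix(entries=np.array([[1]]))
        fit = ck.em_fit(X, q, model="dina")
        phat = X.mean()
        target = 50 * (phat * np.log(phat) + (1 - phat) * np.log(1 - phat))
        assert fit.loglik == pytest.approx(target, abs=1e-3)

    def test_em_matches_direct_maximization_k2_j3(self, q_small, rng):
        """EM solution vs a coarse grid + polished direct maximizer of the
        marginal likelihood (K=2, J=3, N=50): log-likelihood maxima agree
        to three decimals."""
        profiles = ck.generate_profiles(50, 2, rng=rng)
        truth = ck.generate_item_parameters(q_small, 0.15, 0.15, rng)
        X = ck.simulate_responses(truth, profiles, rng).astype(float)
        fit = ck.em_fit(X, q_small, model="gdina", config=ck.EMConfig(tol=1e-7, max_iter=5000))

        # oracle: maximize over logits of (p1(2), p2(2), p3(4)) and softmax pi(4)
        def unpack(x):
            probs = [expit(x[0:2]), expit(x[2:4]), expit(x[4:8])]
            e = np.exp(x[8:12] - x[8:12].max())
            return probs, e / e.sum()

        def neg(x):
            probs, pi = unpack(x)
            return -marginal_loglik(X, q_small, probs, pi)

        best = np.inf
        starts = [rng.standard_normal(12) for _ in range(8)]
        # include a coarse-grid style start at the data-driven point
        starts.append(np.concatenate([np.full(8, 0.0), np.zeros(4)]))
        for x0 in starts:
            res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                    options={"maxiter": 8000, "fatol": 1e-10, "xatol": 1e-8})
            res = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                    options={"maxiter": 8000, "fatol": 1e-12, "xatol": 1e-9})
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-3)


class TestEMProperties:
    def test_loglik_monotone_and_posterior_normalized(self, small_sim):
        q, truth, profiles, X = small_sim
        for model in ("gdina", "dina", "dino", "rrum"):
            fit = ck.em_fit(X, q, model=model)
            diffs = np.diff(fit.loglik_history)
            assert (diffs > -1e-6).all(), f"{model}: log-likelihood decreased"
            assert np.abs(fit.posterior.sum(axis=1) - 1).max() < 1e-10
            assert fit.pi.min() >= 0 and fit.pi.sum() == pytest.approx(1.0)

    def test_refit_from_fitted_parameters_is_fixed_point(self, small_sim):
        q, truth, profiles, X = small_sim
        fit = ck.em_fit(X, q, model="gdina")
        refit = ck.em_fit(X, q, model="gdina", init=fit.irf, init_pi=fit.pi)
        assert refit.n_iter == 1 and refit.converged
        assert refit.max_change < 1e-4

    def test_dina_parameter_recovery_improves_with_n(self):
        q = ck.default_qmatrix(J=15, K=3)
        rmse = {}
        for n in (300, 1500):
            rng = np.random.default_rng(7)
            profiles = ck.generate_profiles(n, 3, rng=rng)
            truth = ck.generate_item_parameters(q, 0.1, 0.1, rng, model="dina")
            X = ck.simulate_responses(truth, profiles, rng)
            fit = ck.em_fit(X, q, model="dina")
            err = np.concatenate([fit.irf.guess - truth.guess, fit.irf.slip - truth.slip])
            rmse[n] = np.sqrt(np.mean(err ** 2))
        assert rmse[1500] < rmse[300]
        assert rmse[1500] < 0.05

    def test_warns_when_n_below_class_count(self, rng):
        q = ck.default_qmatrix(J=10, K=4)
        X = rng.integers(0, 2, size=(10, 10))
        with pytest.warns(UserWarning, match="latent classes"):
            ck.em_fit(X, q, model="dina", config=ck.EMConfig(max_iter=5))

    def test_missing_or_nonbinary_responses_rejected(self, q_small):
        with pytest.raises(ValueError, match="not 0/1"):
            ck.em_fit(np.array([[1, 0, 2]]), q_small)


class TestInformationCriteria:
    def _fake_fit(self, loglik, n_params, n=50):
        q = ck.QMatrix(entries=np.array([[1]]))
        irf = ck.ItemResponseFunction(model="dina", q=q, probs=[[0.2, 0.8]])
        return ck.FitResult(model="dina", irf=irf, pi=np.array([0.5, 0.5]),
                            loglik=loglik, n_params=n_params, n_iter=1, converged=True,
                            max_change=0.0, posterior=np.full((n, 2), 0.5),
                            space=ck.enumerate_patterns(1))

    def test_aic_bic_formulas(self):
        fit = self._fake_fit(loglik=-50.0, n_params=5)
        neg2ll, aic, bic = ck.information_criteria(fit, N=50)
        assert neg2ll == pytest.approx(100.0)
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100 + 5 * np.log(50), abs=1e-6)
        assert bic == pytest.approx(119.56, abs=0.01)

    def test_zero_parameters_degenerate(self):
        fit = self._fake_fit(loglik=-50.0, n_params=0)
        neg2ll, aic, bic = ck.information_criteria(fit, N=50)
        assert aic == bic == neg2ll


class TestLikelihoodRatio:
    def test_model_against_itself_is_null(self, small_sim):
        q, truth, profiles, X = small_sim
        fit = ck.em_fit(X, q, model="dina")
        lr, df, p = ck.likelihood_ratio_test(fit, fit)
        assert lr == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_df_counts_saturated_minus_dina(self, small_sim):
        q, truth, profiles, X = small_sim
        config = ck.EMConfig(max_iter=200)
        full = ck.em_fit(X, q, model="gdina", config=config)
        nested = ck.em_fit(X, q, model="dina", config=config)
        lr, df, p = ck.likelihood_ratio_test(full, nested)
        assert df == int((2 ** q.item_attr_count - 2).sum())
        assert lr >= -1e-6

    def test_gdina_beats_dina_on_saturated_data(self, small_sim):
        q, truth, profiles, X = small_sim
        full = ck.em_fit(X, q, model="gdina")
        nested = ck.em_fit(X, q, model="dina")
        lr, df, p = ck.likelihood_ratio_test(full, nested)
        assert p < 0.001

    def test_non_nested_pair_refused(self, small_sim):
        q, truth, profiles, X = small_sim
        config = ck.EMConfig(max_iter=50)
        dina = ck.em_fit(X, q, model="dina", config=config)
        dino = ck.em_fit(X, q, model="dino", config=config)
        with pytest.raises(ValueError, match="not nested"):
            ck.likelihood_ratio_test(dina, dino)
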