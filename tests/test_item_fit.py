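import numpy as np
import pytest

import cdmkit as ck
from cdmkit.item_fit import fisher_z, observed_pair_tables, predicted_moments


class TestLogOdds:
    def test_identical_tables_give_zero(self):
        assert ck.log_odds_itemfit((40, 10, 10, 40), (40, 10, 10, 40)) == pytest.approx(0.0)

    def test_hand_computed_odds_ratio(self):
        # OR = 40*40/(10*10) = 16
        l = ck.log_odds_itemfit((40, 10, 10, 40), (25, 25, 25, 25))
        assert l == pytest.approx(np.log(16.0), abs=1e-12)
        assert np.log(16.0) == pytest.approx(2.7726, abs=1e-4)

    def test_symmetric_in_the_item_pair(self):
        # transposing the pair swaps n10 and n01: OR unchanged
        a = ck.log_odds_itemfit((30, 5, 20, 45), (25, 25, 25, 25))
        b = ck.log_odds_itemfit((30, 20, 5, 45), (25, 25, 25, 25))
        assert a == pytest.approx(b)

    def test_zero_cell_continuity_correction(self):
        l = ck.log_odds_itemfit((40, 0, 10, 50), (40, 0, 10, 50))
        assert np.isfinite(l) and l == pytest.approx(0.0)


class TestTransformedCorrelation:
    def test_equal_correlations_give_zero(self):
        assert ck.transformed_correlation_itemfit(0.37, 0.37) == pytest.approx(0.0)

    def test_hand_fisher_transform(self):
        r = ck.transformed_correlation_itemfit(0.5, 0.0)
        assert r == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert r == pytest.approx(0.5493, abs=1e-4)

    def test_invariant_under_negating_both(self):
        assert ck.transformed_correlation_itemfit(-0.4, -0.1) == pytest.approx(
            ck.transformed_correlation_itemfit(0.4, 0.1)
        )

    def test_perfect_correlation_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0))


class TestProportionCorrect:
    def test_values(self):
        assert ck.proportion_correct_itemfit(0.6, 0.6) == 0.0
        assert ck.proportion_correct_itemfit(0.60, 0.55) == pytest.approx(0.05)


class TestPredictedMoments:
    def test_single_class_independent_items(self):
        q = ck.QMatrix(entries=np.array([[1], [1]]))
        irf = ck.ItemResponseFunction(model="gdina", q=q, probs=[[0.5, 0.5], [0.5, 0.5]])
        fit = ck.FitResult(model="gdina", irf=irf, pi=np.array([1.0, 0.0]),
                           loglik=0.0, n_params=0, n_iter=1, converged=True, max_change=0.0,
                           posterior=np.array([[1.0, 0.0]]), space=ck.enumerate_patterns(1))
        pred = predicted_moments(fit)
        assert pred["p11"][0, 1] == pytest.approx(0.25)
        assert pred["means"] == pytest.approx([0.5, 0.5])

    def test_two_class_mixture_matches_enumeration(self, rng):
        q = ck.QMatrix(entries=np.array([[1], [1]]))
        p = [rng.uniform(0.1, 0.9, 2), rng.uniform(0.1, 0.9, 2)]
        pi = np.array([0.3, 0.7])
        irf = ck.ItemResponseFunction(model="gdina", q=q, probs=p)
        fit = ck.FitResult(model="gdina", irf=irf, pi=pi, loglik=0.0, n_params=0,
                           n_iter=1, converged=True, max_change=0.0,
                           posterior=np.array([[0.5, 0.5]]), space=ck.enumerate_patterns(1))
        pred = predicted_moments(fit)
        e11 = sum(pi[c] * p[0][c] * p[1][c] for c in range(2))
        mean0 = sum(pi[c] * p[0][c] for c in range(2))
        assert pred["p11"][0, 1] == pytest.approx(e11)
        assert pred["means"][0] == pytest.approx(mean0)


class TestItemFitReport:
    def test_statistics_small_under_true_model(self, rng):
        q = ck.default_qmatrix(J=8, K=2)
        profiles = ck.generate_profiles(2000, 2, rng=rng)
        truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
        X = ck.simulate_responses(truth, profiles, rng)
        fit = ck.em_fit(X, q, model="gdina")
        rep = ck.itemfit_report(fit, X)
        assert rep.items["p"].mean() <= 0.01
        assert (rep.pairs["l"] >= 0).all() and (rep.pairs["r"] >= 0).all()
        assert set(rep.summary.index) == {"l", "r", "p"}
        assert len(rep.pairs) == 8 * 7 // 2

    def test_fit_statistics_shrink_with_sample_size(self):
        q = ck.default_qmatrix(J=10, K=2)
        means = {}
        for n in (500, 5000):
            rng = np.random.default_rng(3)
            profiles = ck.generate_profiles(n, 2, rng=rng)
            truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
            X = ck.simulate_responses(truth, profiles, rng)
            fit = ck.em_fit(X, q, model="gdina")
            rep = ck.itemfit_report(fit, X)
            means[n] = (rep.pairs["l"].mean(), rep.pairs["r"].mean(), rep.items["p"].mean())
        # pair statistics shrink with N; the saturated fit reproduces item
        # means almost exactly at any N, so p is only checked to stay tiny
        for a, b in zip(means[5000][:2], means[500][:2]):
            assert a < b
        assert means[500][2] < 1e-6 and means[5000][2] < 1e-6

    def test_misspecified_dina_shows_larger_residuals(self, rng):
        """DINA fitted to strongly interactive saturated data misfits item
        pairs more than the saturated model does."""
        q = ck.default_qmatrix(J=10, K=2)
        # strongly interactive truth: only full mastery lifts the probability
        probs = []
        for j in range(q.J):
            n = 1 << int(q.item_attr_count[j])
            p = np.full(n, 0.15)
            p[-1] = 0.85
            if n > 2:
                p[1:-1] = 0.2
            probs.append(p)
        truth = ck.ItemResponseFunction(model="gdina", q=q, probs=probs)
        profiles = ck.generate_profiles(1500, 2, rng=rng)
        X = ck.simulate_responses(truth, profiles, rng)
        gdina = ck.em_fit(X, q, model="gdina")
        dino = ck.em_fit(X, q, model="dino")
        rep_g = ck.itemfit_report(gdina, X)
        rep_d = ck.itemfit_report(dino, X)
        assert rep_d.pairs["l"].mean() > rep_g.pairs["l"].mean()
        assert rep_d.pairs["r"].mean() > rep_g.pairs["r"].mean()

    def test_observed_tables_consistent(self, rng):
        X = rng.integers(0, 2, size=(50, 4))
        obs = observed_pair_tables(X)
        total = obs["n11"] + obs["n10"] + obs["n01"] + obs["n00"]
        off_diag = ~np.eye(4, dtype=bool)
        assert (total[off_diag] == 50).all()
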