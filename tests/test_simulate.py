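import numpy as np
import pytest

import cdmkit as ck


class TestGenerateProfiles:
    def test_certain_mastery(self, rng):
        assert ck.generate_profiles(20, 3, p=1.0, rng=rng).all()

    def test_marginal_rate_concentrates(self, rng):
        profiles = ck.generate_profiles(10000, 7, p=0.5, rng=rng)
        means = profiles.mean(axis=0)
        assert ((means > 0.48) & (means < 0.52)).all()

    def test_latent_correlation_induces_phi_correlation(self, rng):
        profiles = ck.generate_profiles(20000, 2, p=0.5, rho=0.99, rng=rng)
        phi = np.corrcoef(profiles.T)[0, 1]
        assert phi > 0.9


class TestGenerateItemParameters:
    def test_single_attribute_item_is_deterministic(self, rng):
        q = ck.QMatrix(entries=np.array([[1, 0]]))
        truth = ck.generate_item_parameters(q, 0.1, 0.2, rng)
        assert truth.probs[0] == pytest.approx([0.1, 0.8])

    def test_interiors_bounded_and_sorted_by_mastery_count(self, rng):
        q = ck.QMatrix(entries=np.array([[1, 1, 1, 1]]))
        truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
        p = truth.probs[0]
        assert p[0] == 0.1 and p[-1] == 0.9
        assert ((p[1:-1] > 0.1) & (p[1:-1] < 0.9)).all()
        counts = np.array([bin(r).count("1") for r in range(16)])
        by_count = [p[counts == c] for c in range(5)]
        assert all(by_count[c].max() <= by_count[c + 1].min() + 1e-12 for c in range(4))

    def test_dina_generation_two_point(self, rng):
        q = ck.QMatrix(entries=np.array([[1, 1, 1]]))
        truth = ck.generate_item_parameters(q, 0.2, 0.3, rng, model="dina")
        assert truth.probs[0][:-1] == pytest.approx(np.full(7, 0.2))
        assert truth.probs[0][-1] == pytest.approx(0.7)

    def test_delta_round_trip_lossless(self, rng):
        q = ck.default_qmatrix(J=10, K=3)
        truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
        for j in range(q.J):
            delta = ck.delta_from_probabilities(truth.probs[j])
            from cdmkit.models import gdina_prob_vector
            assert gdina_prob_vector(delta) == pytest.approx(truth.probs[j], abs=1e-12)

    def test_inconsistent_guess_slip_rejected(self, rng):
        q = ck.default_qmatrix(J=4, K=2)
        with pytest.raises(ValueError, match="guess"):
            ck.generate_item_parameters(q, 0.6, 0.5, rng)


class TestSimulateResponses:
    def test_noise_free_full_mastery_row(self):
        q = ck.default_qmatrix(J=10, K=3)
        truth = ck.generate_item_parameters(q, 0.0, 0.0, np.random.default_rng(0), model="dina")
        X = ck.simulate_responses(truth, np.ones((3, 3), dtype=int), np.random.default_rng(0))
        assert X.all()

    def test_single_class_item_means_concentrate(self, rng):
        q = ck.default_qmatrix(J=10, K=3)
        truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
        profiles = np.tile([1, 0, 1], (10000, 1))
        X = ck.simulate_responses(truth, profiles, rng)
        space = ck.enumerate_patterns(3)
        expected = truth.expand(space)[:, space.index_of([1, 0, 1])]
        assert np.abs(X.mean(axis=0) - expected).max() < 0.02

    def test_fixed_seed_is_bit_identical(self):
        q = ck.default_qmatrix(J=8, K=2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            profiles = ck.generate_profiles(100, 2, rng=rng)
            truth = ck.generate_item_parameters(q, 0.1, 0.1, rng)
            out.append(ck.simulate_responses(truth, profiles, rng))
        assert np.array_equal(out[0], out[1])


class TestRecoveryMetrics:
    def _rep(self, **kw):
        base = {
            "true_guess": np.array([0.1]),
            "est_guess": np.array([0.1]),
            "true_slip": np.array([0.1]),
            "est_slip": np.array([0.1]),
            "true_profiles": np.array([[1, 0]]),
            "est_profiles": np.array([[1, 0]]),
        }
        base.update(kw)
        return base

    def test_perfect_estimates(self):
        rec = ck.recovery_metrics([self._rep()])
        assert rec.rmse_guess == rec.mae_guess == 0.0
        assert rec.pca == rec.pcv == 1.0
        assert rec.pm == pytest.approx([1.0, 1.0])

    def test_single_item_error(self):
        rec = ck.recovery_metrics([self._rep(est_guess=np.array([0.2]))])
        assert rec.rmse_guess == pytest.approx(0.1)
        assert rec.mae_guess == pytest.approx(0.1)

    def test_half_right_vector(self):
        rec = ck.recovery_metrics([self._rep(est_profiles=np.array([[1, 1]]))])
        assert rec.pca == pytest.approx(0.5)
        assert rec.pcv == 0.0
        assert rec.pm == pytest.approx([1.0, 0.0])

    def test_invariants_on_random_input(self, rng):
        reps = []
        for _ in range(4):
            reps.append(
                {
                    "true_guess": rng.uniform(0, 0.3, 10),
                    "est_guess": rng.uniform(0, 0.3, 10),
                    "true_slip": rng.uniform(0, 0.3, 10),
                    "est_slip": rng.uniform(0, 0.3, 10),
                    "true_profiles": rng.integers(0, 2, (50, 4)),
                    "est_profiles": rng.integers(0, 2, (50, 4)),
                }
            )
        rec = ck.recovery_metrics(reps)
        assert rec.rmse_guess >= rec.mae_guess
        assert rec.rmse_slip >= rec.mae_slip
        assert 0 <= rec.pcv <= rec.pca <= 1
        assert (np.diff(rec.pm) <= 1e-12).all()


class TestComparisonStudy:
    def test_smoke_design_end_to_end(self):
        design = ck.SimulationDesign(N=200, J=12, K=3, n_reps=1, seed=5)
        report = ck.run_comparison_study(design)
        assert set(report.recovery.index) == {"gdina", "dina", "dino", "rrum"}
        assert report.n_failures == 0
        assert (report.pm_curves.diff(axis=1).iloc[:, 1:] <= 1e-12).all().all()
        assert (report.recovery["pca"] >= report.recovery["pcv"]).all()
        assert len(report.seeds) == 1

    def test_pca_grows_with_sample_size(self):
        pcas = {}
        for n in (500, 2000):
            design = ck.SimulationDesign(N=n, J=12, K=3, n_reps=2, seed=9,
                                         models=("gdina",))
            pcas[n] = ck.run_comparison_study(design).recovery.loc["gdina", "pca"]
        assert pcas[2000] > pcas[500]

    def test_dina_truth_makes_dina_and_gdina_agree(self):
        design = ck.SimulationDesign(N=2000, J=20, K=3, n_reps=2, seed=11,
                                     generating_model="dina", models=("gdina", "dina"))
        report = ck.run_comparison_study(design)
        assert abs(report.recovery.loc["gdina", "pca"]
                   - report.recovery.loc["dina", "pca"]) < 0.03

    def test_design_validation(self):
        with pytest.raises(ValueError):
            ck.SimulationDesign(guess=0.6, slip=0.5)
        with pytest.raises(ValueError):
            ck.SimulationDesign(generating_model="rrum")
        with pytest.raises(ValueError):
            ck.SimulationDesign(bogus_field=1)

    def test_qmatrix_mismatch_rejected(self):
        design = ck.SimulationDesign(N=100, J=12, K=3, n_reps=1)
        with pytest.raises(ValueError, match="design asks"):
            ck.run_comparison_study(design, q=ck.default_qmatrix(J=10, K=3))
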