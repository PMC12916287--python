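import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from deptraj.basis import FPBasis, build_fp_basis
from deptraj.simulate import GeneratorConfig, generate_cohort
from deptraj.smfq import fitting_sample, score_table
from deptraj.trajectory import (
    FitValidationError,
    TrajectoryModel,
    marginal_loglik,
    posterior_probs,
    predict_class,
)

from conftest import make_two_class_data


def brute_force_loglik(df, coef, mixing, sigma2, tau2, omega, basis):
    """Direct mixture likelihood via explicit per-subject covariance
    matrices and scipy's multivariate normal density."""
    total = 0.0
    for _, grp in df.groupby("subject_id"):
        grp = grp.dropna(subset=["score"]).sort_values("age")
        if len(grp) == 0:
            continue
        X = build_fp_basis(grp["age"].to_numpy(), basis)
        y = grp["score"].to_numpy()
        n = len(y)
        lik = 0.0
        for g in range(len(mixing)):
            V = sigma2 * np.eye(n) + (omega[g] ** 2) * tau2 * np.ones((n, n))
            lik += mixing[g] * multivariate_normal.pdf(y, mean=X @ coef[g], cov=V)
        total += np.log(lik)
    return total


class TestMarginalLoglik:
    def test_single_class_equals_sum_of_univariate_densities(self):
        df = make_two_class_data(n=20, means=(5.0, 5.0), seed=1)
        basis = FPBasis((1, 2))
        X = build_fp_basis(df["age"].to_numpy(), basis)
        y = df["score"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = float(np.mean((y - X @ beta) ** 2))
        expected = np.sum(
            -0.5 * (np.log(2 * np.pi * sigma2) + (y - X @ beta) ** 2 / sigma2)
        )
        got = marginal_loglik(df, beta[None, :], [1.0], sigma2, basis=basis)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_duplicated_class_collapses_to_single(self):
        df = make_two_class_data(n=15, seed=2)
        basis = FPBasis((1,))
        coef = np.array([[3.0, 1.0]])
        one = marginal_loglik(df, coef, [1.0], 2.0, basis=basis)
        two = marginal_loglik(
            df, np.vstack([coef, coef]), [0.5, 0.5], 2.0, basis=basis
        )
        assert two == pytest.approx(one, rel=1e-12)

    @pytest.mark.parametrize("tau2, omega", [(0.0, (1.0, 1.0)), (1.7, (1.0, 0.6))])
    def test_matches_brute_force_covariance_oracle(self, rng, tau2, omega):
        basis = FPBasis((1, 2))
        rows = []
        for i in range(5):
            for a in (10.0, 16.0, 25.0):
                rows.append(
                    {"subject_id": i, "age": a, "score": rng.normal(8, 4)}
                )
        df = pd.DataFrame(rows)
        coef = rng.normal(0, 2, size=(2, 3))
        mixing = np.array([0.3, 0.7])
        sigma2 = 2.3
        expected = brute_force_loglik(
            df, coef, mixing, sigma2, tau2, np.asarray(omega), basis
        )
        got = marginal_loglik(
            df, coef, mixing, sigma2, tau2, np.asarray(omega), basis
        )
        assert got == pytest.approx(expected, rel=1e-9)

    def test_random_small_instances_against_oracle(self, rng):
        basis = FPBasis((1,))
        for trial in range(10):
            n_subj = int(rng.integers(2, 10))
            rows = []
            for i in range(n_subj):
                for a in sorted(rng.choice([10, 13, 17, 21], size=int(rng.integers(1, 5)), replace=False)):
                    rows.append({"subject_id": i, "age": float(a), "score": rng.normal(5, 3)})
            df = pd.DataFrame(rows)
            G = int(rng.integers(1, 4))
            coef = rng.normal(0, 2, size=(G, 2))
            mixing = rng.dirichlet(np.ones(G))
            sigma2 = float(rng.uniform(0.5, 4.0))
            tau2 = float(rng.uniform(0.0, 2.0))
            omega = np.concatenate([[1.0], rng.uniform(0.5, 1.5, G - 1)])
            expected = brute_force_loglik(df, coef, mixing, sigma2, tau2, omega, basis)
            got = marginal_loglik(df, coef, mixing, sigma2, tau2, omega, basis)
            assert got == pytest.approx(expected, rel=1e-8)


class TestFit:
    def test_single_class_gbtm_equals_pooled_ols(self):
        df = make_two_class_data(n=40, means=(4.0, 9.0), seed=3)
        basis = FPBasis((1, 2))
        model = TrajectoryModel(
            n_classes=1, basis=basis, n_starts=2, random_state=0
        ).fit(df)
        X = build_fp_basis(df["age"].to_numpy(), basis)
        beta, *_ = np.linalg.lstsq(X, df["score"].to_numpy(), rcond=None)
        np.testing.assert_allclose(model.coef_[0], beta, atol=1e-6)

    def test_two_class_noise_free_recovery(self):
        df = make_two_class_data(n=500, means=(2.0, 20.0), residual_sd=0.5, seed=4)
        model = TrajectoryModel(
            n_classes=2, basis=FPBasis((1,)), n_starts=10, random_state=1
        ).fit(df)
        means_at_15 = np.sort(
            build_fp_basis(np.array([15.0]), model.basis) @ model.coef_.T
        ).ravel()
        assert abs(means_at_15[0] - 2.0) < 0.1
        assert abs(means_at_15[1] - 20.0) < 0.1
        true_pi = np.mean(df.groupby("subject_id")["true_class"].first() == 1)
        assert abs(np.max(model.mixing_) - max(true_pi, 1 - true_pi)) < 0.01

    def test_refit_same_seed_is_deterministic(self):
        df = make_two_class_data(n=80, seed=5)
        m1 = TrajectoryModel(n_classes=2, n_starts=5, random_state=9).fit(df)
        m2 = TrajectoryModel(n_classes=2, n_starts=5, random_state=9).fit(df)
        assert m1.loglik_ == pytest.approx(m2.loglik_, abs=1e-10)
        np.testing.assert_array_equal(m1.coef_, m2.coef_)

    def test_reported_loglik_matches_recomputation(self):
        df = make_two_class_data(n=60, seed=6)
        model = TrajectoryModel(n_classes=2, n_starts=5, random_state=2).fit(df)
        assert model.score(df) == pytest.approx(model.loglik_, abs=1e-6)

    def test_classes_ordered_by_descending_share(self):
        df = make_two_class_data(n=200, pi=0.25, seed=7)
        model = TrajectoryModel(n_classes=2, n_starts=5, random_state=3).fit(df)
        assert model.mixing_[0] >= model.mixing_[1]

    def test_too_many_classes_rejected(self):
        df = make_two_class_data(n=3, seed=8)
        with pytest.raises(FitValidationError):
            TrajectoryModel(n_classes=5, random_state=0).fit(df)

    def test_empty_data_rejected(self):
        df = pd.DataFrame({"subject_id": [], "age": [], "score": []})
        with pytest.raises(FitValidationError):
            TrajectoryModel(n_classes=1, random_state=0).fit(df)

    def test_missing_seed_rejected(self):
        df = make_two_class_data(n=10, seed=9)
        with pytest.raises(FitValidationError, match="seed"):
            TrajectoryModel(n_classes=2, random_state=None).fit(df)

    def test_gmm_common_intercept_recovers_separated_classes(self):
        rng = np.random.default_rng(10)
        rows = []
        for i in range(250):
            cls = int(rng.random() < 0.4)
            b = rng.normal(0, 1.0)
            for a in (10.0, 14.0, 18.0, 22.0):
                rows.append(
                    {
                        "subject_id": i,
                        "age": a,
                        "score": (3.0, 15.0)[cls] + b + rng.normal(0, 1.0),
                    }
                )
        df = pd.DataFrame(rows)
        model = TrajectoryModel(
            n_classes=2,
            basis=FPBasis((1,)),
            random_effects="common_intercept",
            n_starts=5,
            random_state=4,
        ).fit(df)
        intercept_means = np.sort(
            (build_fp_basis(np.array([16.0]), model.basis) @ model.coef_.T).ravel()
        )
        assert abs(intercept_means[0] - 3.0) < 0.5
        assert abs(intercept_means[1] - 15.0) < 0.5
        assert 0.2 < model.tau2_ < 3.0


class TestPosteriors:
    def test_single_class_posteriors_are_one(self):
        df = make_two_class_data(n=20, seed=11)
        model = TrajectoryModel(n_classes=1, n_starts=2, random_state=0).fit(df)
        post = model.predict_proba(df)
        np.testing.assert_allclose(post.probabilities, 1.0)

    def test_rows_sum_to_one(self, rng):
        df = make_two_class_data(n=50, seed=12)
        model = TrajectoryModel(n_classes=3, n_starts=5, random_state=5).fit(df)
        post = model.predict_proba(df)
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(
            post.modal_class, np.argmax(post.probabilities, axis=1) + 1
        )

    def test_subject_between_symmetric_classes_gets_half(self):
        df = make_two_class_data(n=400, means=(0.0, 10.0), pi=0.5,
                                 residual_sd=1.0, seed=13)
        model = TrajectoryModel(
            n_classes=2, basis=FPBasis((1,)), n_starts=5, random_state=6
        ).fit(df)
        # construct a subject lying exactly between the two fitted curves
        ages = np.array([10.0, 15.0, 20.0])
        Xm = build_fp_basis(ages, model.basis)
        midline = (Xm @ model.coef_.T).mean(axis=1)
        new = pd.DataFrame(
            {"subject_id": "mid", "age": ages, "score": midline}
        )
        post = model.predict_proba(new)
        expected = model.mixing_  # symmetric likelihoods leave the prior
        np.testing.assert_allclose(post.probabilities[0], expected, atol=1e-6)

    def test_predict_class_matches_posterior_probs_in_sample(self):
        df = make_two_class_data(n=40, seed=14)
        model = TrajectoryModel(n_classes=2, n_starts=5, random_state=7).fit(df)
        a = posterior_probs(model, df)
        b = predict_class(model, df)
        np.testing.assert_allclose(a.probabilities, b.probabilities)

    def test_subject_with_no_occasions_gets_prior_and_flag(self):
        df = make_two_class_data(n=30, seed=15)
        model = TrajectoryModel(n_classes=2, n_starts=5, random_state=8).fit(df)
        new = pd.DataFrame(
            {"subject_id": ["x", "x"], "age": [10.0, 12.0], "score": [np.nan, np.nan]}
        )
        post = model.predict_proba(new)
        assert post.prior_fallback[0]
        np.testing.assert_allclose(post.probabilities[0], model.mixing_)

    def test_one_occasion_subject_is_predictable(self):
        df = make_two_class_data(n=30, seed=16)
        model = TrajectoryModel(n_classes=2, n_starts=5, random_state=8).fit(df)
        new = pd.DataFrame({"subject_id": ["y"], "age": [15.0], "score": [2.0]})
        post = model.predict_proba(new)
        assert not post.prior_fallback[0]
        assert post.probabilities[0].sum() == pytest.approx(1.0)


class TestRecoveryOnDefaultCohort:
    def test_four_class_gbtm_recovers_planted_structure(self):
        """Planted mixing proportions and curves on default cohorts."""
        pi_errs, curve_rms = [], []
        for seed in (101, 102, 103):
            cfg = GeneratorConfig(n_subjects=2000, seed=seed)
            fit_df = fitting_sample(score_table(generate_cohort(cfg).occasions))
            model = TrajectoryModel(n_classes=4, random_state=seed).fit(fit_df)
            planted = np.sort(np.asarray(cfg.class_proportions))[::-1]
            pi_errs.append(np.max(np.abs(model.mixing_ - planted)))
            ages = np.asarray(cfg.occasion_ages, float)
            X = build_fp_basis(ages, cfg.trajectory_basis)
            true_curves = (X @ cfg.trajectories().T).T  # class x age
            est_curves = (X @ model.coef_.T).T
            # match estimated to planted classes by curve proximity
            for est in est_curves:
                d = np.sqrt(((true_curves - est) ** 2).mean(axis=1))
                curve_rms.append(d.min())
        assert np.mean(pi_errs) < 0.02
        assert np.mean(curve_rms) < 0.5

    def test_json_roundtrip_preserves_posteriors(self, default_fit_sample):
        model = TrajectoryModel(
            n_classes=2, n_starts=5, random_state=0
        ).fit(default_fit_sample)
        clone = TrajectoryModel.from_json(model.to_json())
        a = model.predict_proba(default_fit_sample).probabilities
        b = clone.predict_proba(default_fit_sample).probabilities
        np.testing.assert_allclose(a, b, atol=1e-12)
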