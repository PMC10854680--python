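"""Kernels, the privileged correction matrix, and both SMO solvers."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sepsislupi.exceptions import InputError, ParameterError, TrainingError
from sepsislupi.svmplus import (
    KernelConfig,
    SvmPlusHyperparams,
    build_correction_matrix,
    decision_scores,
    fit_svm_baseline,
    fit_svmplus,
    gaussian_kernel_matrix,
    kernel_matrix,
    solve_svmplus_dual,
)

from oracles import csvm_qp, oneclass_qp


class TestGaussianKernel:
    def test_self_similarity_is_one_or_two_augmented(self, rng):
        x = rng.normal(size=(1, 4))
        assert gaussian_kernel_matrix(x, x, KernelConfig(scale=2.0))[0, 0] == 1.0
        aug = KernelConfig(scale=2.0, augmented=True)
        assert gaussian_kernel_matrix(x, x, aug)[0, 0] == 2.0

    def test_distant_points_decay_to_floor(self):
        a, b = np.array([[0.0, 0.0]]), np.array([[1e4, 1e4]])
        assert gaussian_kernel_matrix(a, b, KernelConfig(scale=1.0))[0, 0] < 1e-12
        aug = KernelConfig(scale=1.0, augmented=True)
        assert gaussian_kernel_matrix(a, b, aug)[0, 0] == pytest.approx(1.0)

    def test_kernel_matrix_is_psd_and_symmetric(self, rng):
        X = rng.normal(size=(5, 3))
        K = gaussian_kernel_matrix(X, X, KernelConfig(scale=1.5, augmented=True))
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            gaussian_kernel_matrix(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)),
                                   KernelConfig())


class TestCorrectionMatrix:
    def test_explicit_equals_kernelized_on_linear_features(self, rng):
        hp = SvmPlusHyperparams(C=2.0, gamma=1.0)
        P = rng.normal(size=(6, 3))  # rows are privileged samples
        G_kernelized = build_correction_matrix(P, hp)
        Pm = P.T  # columns z_i^*
        G_explicit = Pm.T @ np.linalg.solve(
            hp.gamma * np.eye(3) + hp.C * (Pm @ Pm.T), Pm
        )
        np.testing.assert_allclose(G_kernelized, G_explicit, atol=1e-10)

    def test_large_gamma_kills_the_correction(self, rng):
        P = rng.normal(size=(6, 3))
        hp = SvmPlusHyperparams(C=2.0, gamma=1e12)
        assert np.linalg.norm(build_correction_matrix(P, hp)) <= 1e-6

    def test_identity_kernel_gives_half_identity(self):
        hp = SvmPlusHyperparams(C=1.0, gamma=1.0)
        G = build_correction_matrix(None, hp, Kstar=np.eye(5))
        np.testing.assert_allclose(G, 0.5 * np.eye(5), atol=1e-12)

    def test_correction_is_psd(self, rng):
        hp = SvmPlusHyperparams(C=3.0, gamma=0.5)
        X = rng.normal(size=(8, 4))
        Kstar = kernel_matrix(X, X, KernelConfig(scale=1.0))
        G = build_correction_matrix(None, hp, Kstar=Kstar)
        assert np.linalg.eigvalsh(G).min() >= -1e-8


class TestOneClassDual:
    def test_identity_q_gives_uniform_alpha(self):
        np.testing.assert_allclose(solve_svmplus_dual(np.eye(4), 0.5), 0.5)

    def test_nu_one_saturates_the_box(self):
        np.testing.assert_allclose(solve_svmplus_dual(np.eye(3), 1.0), 1.0)

    def test_random_psd_problems_match_qp_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(5, 31))
            A = rng.normal(size=(n, n))
            Q = A @ A.T / n + 1e-3 * np.eye(n)
            nu = float(rng.choice([0.3, 0.5, 0.8]))
            alpha = solve_svmplus_dual(Q, nu)
            assert abs(alpha.sum() - nu * n) <= 1e-6
            assert alpha.min() >= -1e-12 and alpha.max() <= 1 + 1e-12
            obj = 0.5 * alpha @ Q @ alpha
            obj_oracle, _ = oneclass_qp(Q, nu)
            assert obj <= obj_oracle + 1e-6

    def test_infeasible_nu_rejected(self):
        with pytest.raises(ParameterError):
            solve_svmplus_dual(np.eye(3), 1.5)


class TestSvmPlusFit:
    def test_two_point_toy_problem_separates(self):
        X = np.array([[0.0], [1.0]])
        Xstar = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        model = fit_svmplus(X, Xstar, y, SvmPlusHyperparams(regular_scale=1.0))
        assert np.array_equal(model.predict(X), [-1, 1])

    def test_zero_privileged_features_reduce_to_plain_dual(self, rng):
        """All-zero X* with a linear privileged kernel gives G = 0."""
        n = 14
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        hp = SvmPlusHyperparams(C=2.0, regular_scale=2.0)
        plain = fit_svmplus(X, np.zeros((n, 2)), y, hp, privileged_kernel_kind="linear")
        K = kernel_matrix(X, X, KernelConfig(scale=2.0, augmented=True))
        alpha_H = solve_svmplus_dual(K * np.outer(y, y), hp.nu)
        np.testing.assert_allclose(plain.alpha, alpha_H, atol=1e-6)

    def test_dual_objective_matches_qp_oracle_on_synthetic_task(self, rng):
        n = 20
        X = rng.normal(size=(n, 4))
        Xstar = X[:, :2] + 0.1 * rng.normal(size=(n, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        hp = SvmPlusHyperparams(C=2.0, gamma=0.7, nu=0.5, regular_scale=2.0,
                                privileged_scale=1.4)
        model = fit_svmplus(X, Xstar, y, hp)
        K = kernel_matrix(X, X, KernelConfig(scale=2.0, augmented=True))
        Kstar = kernel_matrix(Xstar, Xstar, KernelConfig(scale=1.4))
        Q = K * np.outer(y, y) + build_correction_matrix(None, hp, Kstar=Kstar)
        obj = 0.5 * model.alpha @ Q @ model.alpha
        obj_oracle, _ = oneclass_qp(Q, hp.nu)
        assert obj <= obj_oracle + 1e-6

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(TrainingError):
            fit_svmplus(X, X, np.ones(5), SvmPlusHyperparams())

    def test_vanishing_pi_limit_as_gamma_grows(self, rng):
        """gamma -> inf recovers the correction-free score ranking."""
        n = 24
        X = rng.normal(size=(n, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=n) > 0, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        Xstar = rng.normal(size=(n, 2))
        Xtest = rng.normal(size=(15, 3))
        base = fit_svmplus(X, np.zeros((n, 1)), y,
                           SvmPlusHyperparams(regular_scale=2.0),
                           privileged_kernel_kind="linear")
        huge = fit_svmplus(X, Xstar, y,
                           SvmPlusHyperparams(gamma=1e10, regular_scale=2.0))
        rho = spearmanr(base.decision_function(Xtest), huge.decision_function(Xtest)).statistic
        assert rho >= 0.999


class TestLupiBenchmark:
    def test_clean_privileged_view_does_not_hurt(self):
        """Directional sanity: with privileged features that are a denoised
        copy of the label signal, SVM+ stays within 0.01 AUROC of SVM."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        svm_aurocs, svmplus_aurocs = [], []
        for _ in range(30):
            n, d = 60, 6
            latent = rng.normal(size=n)
            y = np.where(latent > 0, 1.0, -1.0)
            X = latent[:, None] + rng.normal(0, 2.0, size=(n, d))
            Xstar = latent[:, None] + rng.normal(0, 0.2, size=(n, 2))
            Xtest = latent[:30, None] + rng.normal(0, 2.0, size=(30, d))
            ytest = y[:30]
            svm = fit_svm_baseline(X, y, C=1.0, scale=np.sqrt(d))
            svm_aurocs.append(roc_auc_score(ytest, svm.decision_function(Xtest)))
            hp = SvmPlusHyperparams(C=1.0, gamma=1.0, nu=0.5,
                                    regular_scale=np.sqrt(d),
                                    privileged_scale=np.sqrt(2))
            plus = fit_svmplus(X, Xstar, y, hp)
            svmplus_aurocs.append(roc_auc_score(ytest, plus.decision_function(Xtest)))
        assert np.mean(svmplus_aurocs) >= np.mean(svm_aurocs) - 0.01


class TestDecisionScores:
    def test_scores_match_naive_double_loop(self, rng):
        n = 20
        X = rng.normal(size=(n, 3))
        Xstar = rng.normal(size=(n, 2))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        hp = SvmPlusHyperparams(regular_scale=1.7)
        model = fit_svmplus(X, Xstar, y, hp)
        Xtest = rng.normal(size=(7, 3))
        scores = decision_scores(model, Xtest)
        naive = np.zeros(7)
        for t in range(7):
            for i in range(n):
                k = np.exp(-np.sum((X[i] - Xtest[t]) ** 2) / hp.regular_scale**2) + 1.0
                naive[t] += model.alpha[i] * y[i] * k
        np.testing.assert_allclose(scores, naive, atol=1e-10)

    def test_score_scaling_preserves_auroc(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, 1, -1)
        labels[:2] = [1, -1]
        assert roc_auc_score(labels, scores) == roc_auc_score(labels, 5.0 * scores)


class TestSvmBaseline:
    def test_separable_points_classified_at_large_c(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model = fit_svm_baseline(X, y, C=100.0, scale=2.0)
        assert np.array_equal(model.predict(X), y)

    def test_dual_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(31)
        n = 15
        X = rng.normal(size=(n, 3))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        for C in (0.5, 2.0, 20.0):
            model = fit_svm_baseline(X, y, C=C, scale=1.5)
            K = kernel_matrix(X, X, KernelConfig(scale=1.5))
            obj_oracle, _ = csvm_qp(K * np.outer(y, y), y, C)
            assert model.dual_objective() <= obj_oracle + 1e-6
            assert abs(np.dot(model.alpha, y)) <= 1e-9
            assert model.alpha.min() >= 0 and model.alpha.max() <= C + 1e-12

    def test_decision_function_matches_sklearn(self, rng):
        from sklearn.svm import SVC

        n = 30
        X = rng.normal(size=(n, 4))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        model = fit_svm_baseline(X, y, C=2.0, scale=1.5)
        sk = SVC(C=2.0, gamma=1 / 1.5**2, tol=1e-8).fit(X, y)
        Xt = rng.normal(size=(10, 4))
        np.testing.assert_allclose(
            model.decision_function(Xt), sk.decision_function(Xt), atol=1e-4
        )

    def test_tiny_c_floors_all_duals(self, rng):
        n = 12
        X = rng.normal(size=(n, 2))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        model = fit_svm_baseline(X, y, C=1e-6, scale=1.0)
        # with a vanishing box every dual that can be at the ceiling is
        n_pos, n_neg = (y > 0).sum(), (y < 0).sum()
        at_box = np.isclose(model.alpha, 1e-6).sum()
        assert at_box >= 2 * min(n_pos, n_neg) - 2
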