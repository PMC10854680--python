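"""Soft-margin SVM and the SVM+ classifier for learning using privileged
information (LUPI).

In LUPI every training case carries, besides its regular feature vector x,
a privileged vector x* that exists only at training time (here: signal and
EHR data from after the prediction moment).  SVM+ replaces the free slack
variables of the soft-margin SVM by a linear function of the privileged
space, so privileged similarity regularises which training points may claim
slack.  After mapping to kernel space and absorbing the bias into an
augmented feature ([z, 1]), the squared-hinge formulation collapses to a
single quadratic dual

    min_a  1/2 a' (H + G) a,   H = K~ o (y y'),   G = K* (gamma I + C K*)^-1,

with K~ the augmented regular kernel and K* the privileged kernel; the
explicit-feature form G = P'(gamma I + C P P')^-1 P equals the kernelised
form by the push-through identity.  The dual is solved in the
one-class-SVM form (sum a = nu n, 0 <= a <= 1) by a pairwise SMO working-set
method; rescaling a leaves the score ranking unchanged, so nu acts as a
normalisation.

The comparison baseline is the ordinary Gaussian-kernel C-SVM with hinge
loss and explicit bias, solved by a two-set (most-violating-pair) SMO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InputError, ParameterError, TrainingError

__all__ = [
    "KernelConfig",
    "SvmPlusHyperparams",
    "gaussian_kernel_matrix",
    "kernel_matrix",
    "build_correction_matrix",
    "solve_svmplus_dual",
    "SvmPlusModel",
    "fit_svmplus",
    "decision_scores",
    "SvmModel",
    "fit_svm_baseline",
]


@dataclass(frozen=True)
class KernelConfig:
    """A kernel with bandwidth ``scale`` and optional bias absorption.

    ``kind="gaussian"`` gives k(x, x') = exp(-||x - x'||^2 / scale^2);
    ``kind="linear"`` gives x . x' (used for oracle checks of the privileged
    correction).  With ``augmented=True`` every kernel value gains +1, which
    is the kernel of the augmented feature [z, 1] and absorbs the bias term.
    """

    scale: float = 1.0
    augmented: bool = False
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "linear"):
            raise ParameterError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.scale <= 0:
            raise ParameterError("gaussian kernel scale must be positive")


def gaussian_kernel_matrix(
    A: np.ndarray, B: np.ndarray, cfg: KernelConfig
) -> np.ndarray:
    """Gaussian kernel matrix between row-sample matrices A and B."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    sq = cdist(A, B, metric="sqeuclidean")
    K = np.exp(-sq / (cfg.scale**2))
    if cfg.augmented:
        K = K + 1.0
    return K


def kernel_matrix(A: np.ndarray, B: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Kernel matrix for either kernel kind of :class:`KernelConfig`."""
    if cfg.kind == "gaussian":
        return gaussian_kernel_matrix(A, B, cfg)
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"feature dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    K = A @ B.T
    if cfg.augmented:
        K = K + 1.0
    return K


@dataclass(frozen=True)
class SvmPlusHyperparams:
    """SVM+ hyperparameters.

    ``C`` is the slack penalty, ``gamma`` the privileged-space regulariser
    (large gamma shrinks the correction G to zero), ``nu`` the one-class
    dual mass parameter, and the two scales are the Gaussian bandwidths of
    the regular and privileged kernels.
    """

    C: float = 1.0
    gamma: float = 1.0
    nu: float = 0.5
    regular_scale: float = 1.0
    privileged_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ParameterError("C and gamma must be positive")
        if not 0 < self.nu <= 1:
            raise ParameterError("nu must be in (0, 1]")
        if self.regular_scale <= 0 or self.privileged_scale <= 0:
            raise ParameterError("kernel scales must be positive")


def build_correction_matrix(
    Pstar: np.ndarray | None,
    hp: SvmPlusHyperparams,
    *,
    Kstar: np.ndarray | None = None,
) -> np.ndarray:
    """The privileged correction G as an n x n matrix.

    Either ``Pstar`` (n x d privileged feature rows, linear kernel) or a
    precomputed privileged kernel ``Kstar`` may be given.  The computation
    uses the kernelised form G = K*(gamma I + C K*)^{-1}, which for linear
    features agrees with the explicit form P'(gamma I + C P P')^{-1} P by
    the push-through identity and supports nonlinear privileged kernels.
    """
    if Kstar is None:
        if Pstar is None:
            raise InputError("provide privileged features or a privileged kernel")
        Pstar = np.atleast_2d(np.asarray(Pstar, dtype=np.float64))
        Kstar = Pstar @ Pstar.T
    Kstar = np.asarray(Kstar, dtype=np.float64)
    n = Kstar.shape[0]
    system = hp.gamma * np.eye(n) + hp.C * Kstar
    G = np.linalg.solve(system, Kstar)  # (gamma I + C K*)^-1 K* = K*(...)^-1
    return 0.5 * (G + G.T)  # symmetrise away solver round-off


def solve_svmplus_dual(
    Q: np.ndarray,
    nu: float,
    tol: float = 1e-8,
    max_updates: int = 200_000,
) -> np.ndarray:
    """Minimise 1/2 a'Qa subject to sum(a) = nu*n, 0 <= a <= 1.

    Pairwise SMO on the simplex-with-box constraint: at each step mass moves
    from the coordinate with the largest gradient (among those that can
    shrink) to the one with the smallest (among those that can grow), with
    the exact line-search step.  Pair selection is first-index deterministic
    on ties; iteration stops when the KKT violation drops below ``tol``.
    """
    Q = np.asarray(Q, dtype=np.float64)
    n = Q.shape[0]
    if Q.shape != (n, n):
        raise InputError("Q must be square")
    if not 0 < nu <= 1:
        raise ParameterError(f"nu must be in (0, 1], got {nu}")
    alpha = np.full(n, nu)
    grad = Q @ alpha
    eps_box = 1e-12
    for _ in range(max_updates):
        can_up = alpha < 1.0 - eps_box
        can_dn = alpha > eps_box
        if not can_up.any() or not can_dn.any():
            break
        gi = np.where(can_up, grad, np.inf)
        gj = np.where(can_dn, grad, -np.inf)
        i = int(np.argmin(gi))
        j = int(np.argmax(gj))
        violation = grad[j] - grad[i]
        if violation <= tol or i == j:
            break
        kappa = Q[i, i] + Q[j, j] - 2.0 * Q[i, j]
        step = violation / kappa if kappa > 1e-14 else np.inf
        step = min(step, 1.0 - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        grad += step * (Q[:, i] - Q[:, j])
    return alpha


@dataclass(frozen=True)
class SvmPlusModel:
    """A fitted SVM+ classifier (stores the training set; kernels are
    recomputed at prediction time)."""

    alpha: np.ndarray
    y: np.ndarray
    X: np.ndarray
    hyperparams: SvmPlusHyperparams
    regular_kernel: KernelConfig
    privileged_kernel: KernelConfig

    def decision_function(self, Xtest: np.ndarray) -> np.ndarray:
        return decision_scores(self, Xtest)

    def predict(self, Xtest: np.ndarray) -> np.ndarray:
        scores = self.decision_function(Xtest)
        return np.where(scores >= 0.0, 1, -1)


def fit_svmplus(
    X: np.ndarray,
    Xstar: np.ndarray,
    y: np.ndarray,
    hp: SvmPlusHyperparams,
    privileged_kernel_kind: str = "gaussian",
) -> SvmPlusModel:
    """Fit SVM+ from regular features X, privileged features Xstar, labels y.

    The regular kernel is the augmented Gaussian (bias absorbed); the
    privileged kernel is Gaussian by default or linear for oracle work.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != Xstar.shape[0] or X.shape[0] != y.size:
        raise InputError("X, Xstar and y must be row-aligned")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InputError("labels must be in {-1, +1}")
    if np.unique(y).size < 2:
        raise TrainingError("training requires both classes")
    reg_cfg = KernelConfig(scale=hp.regular_scale, augmented=True, kind="gaussian")
    priv_cfg = KernelConfig(
        scale=hp.privileged_scale, augmented=False, kind=privileged_kernel_kind
    )
    H = kernel_matrix(X, X, reg_cfg) * np.outer(y, y)
    Kstar = kernel_matrix(Xstar, Xstar, priv_cfg)
    G = build_correction_matrix(None, hp, Kstar=Kstar)
    alpha = solve_svmplus_dual(H + G, hp.nu)
    return SvmPlusModel(
        alpha=alpha,
        y=y,
        X=X,
        hyperparams=hp,
        regular_kernel=reg_cfg,
        privileged_kernel=priv_cfg,
    )


def decision_scores(model: SvmPlusModel, Xtest: np.ndarray) -> np.ndarray:
    """Raw scores f(x) = sum_i a_i y_i K~(x_i, x); bias absorbed in K~."""
    Xtest = np.atleast_2d(np.asarray(Xtest, dtype=np.float64))
    K = kernel_matrix(model.X, Xtest, model.regular_kernel)
    return (model.alpha * model.y) @ K


@dataclass(frozen=True)
class SvmModel:
    """A fitted soft-margin Gaussian-kernel SVM with explicit bias."""

    alpha: np.ndarray
    y: np.ndarray
    X: np.ndarray
    bias: float
    C: float
    kernel: KernelConfig

    def decision_function(self, Xtest: np.ndarray) -> np.ndarray:
        Xtest = np.atleast_2d(np.asarray(Xtest, dtype=np.float64))
        K = kernel_matrix(self.X, Xtest, self.kernel)
        return (self.alpha * self.y) @ K + self.bias

    def predict(self, Xtest: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(Xtest) >= 0.0, 1, -1)

    def dual_objective(self) -> float:
        """1/2 a'Ha - 1'a, the quantity the SMO minimises."""
        K = kernel_matrix(self.X, self.X, self.kernel)
        H = K * np.outer(self.y, self.y)
        return 0.5 * self.alpha @ H @ self.alpha - self.alpha.sum()


def fit_svm_baseline(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    scale: float = 1.0,
    tol: float = 1e-8,
    max_updates: int = 200_000,
) -> SvmModel:
    """Hinge-loss C-SVM dual solved by most-violating-pair SMO.

    Solves min 1/2 a'Ha - 1'a s.t. y'a = 0, 0 <= a <= C, with
    H = K o (y y'), and recovers the bias from the final KKT interval.
    """
    if C <= 0:
        raise ParameterError("C must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InputError("labels must be in {-1, +1}")
    if np.unique(y).size < 2:
        raise TrainingError("training requires both classes")
    cfg = KernelConfig(scale=scale, augmented=False, kind="gaussian")
    K = kernel_matrix(X, X, cfg)
    H = K * np.outer(y, y)
    n = y.size
    alpha = np.zeros(n)
    grad = -np.ones(n)  # H @ alpha - 1
    eps_box = 1e-12 * max(C, 1.0)
    m_up = M_dn = 0.0
    for _ in range(max_updates):
        pos = y > 0
        up_mask = np.where(pos, alpha < C - eps_box, alpha > eps_box)
        dn_mask = np.where(pos, alpha > eps_box, alpha < C - eps_box)
        F = -y * grad
        Fi = np.where(up_mask, F, -np.inf)
        Fj = np.where(dn_mask, F, np.inf)
        i = int(np.argmax(Fi))
        j = int(np.argmin(Fj))
        m_up = Fi[i]
        M_dn = Fj[j]
        if not np.isfinite(m_up) or not np.isfinite(M_dn) or m_up - M_dn <= tol:
            break
        kappa = K[i, i] + K[j, j] - 2.0 * K[i, j]
        t = (m_up - M_dn) / kappa if kappa > 1e-14 else np.inf
        # box caps along alpha_i += y_i t, alpha_j -= y_j t
        cap_i = (C - alpha[i]) if y[i] > 0 else alpha[i]
        cap_j = alpha[j] if y[j] > 0 else (C - alpha[j])
        t = min(t, cap_i, cap_j)
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        # d(grad)/dt along this direction: H[:,i] y_i - H[:,j] y_j = y*(K_i - K_j)
        grad += t * y * (K[:, i] - K[:, j])
        np.clip(alpha, 0.0, C, out=alpha)
    bias = 0.5 * (m_up + M_dn) if np.isfinite(m_up) and np.isfinite(M_dn) else 0.0
    return SvmModel(alpha=alpha, y=y, X=X, bias=bias, C=C, kernel=cfg)
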