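"""Independent brute-force/QP oracles used by the test suite only.

These deliberately avoid the package's own algorithms: the taut-string tube
problem is solved as a bounded-variable least-squares QP, and the SVM duals
with scipy's trust-region constrained minimiser with exact derivatives.
"""

import numpy as np
from scipy.optimize import LinearConstraint, lsq_linear, minimize
from scipy.sparse import diags


def taut_string_qp(f: np.ndarray, eps: float):
    """Minimise sum((g[i+1]-g[i])^2) s.t. |g - f| <= eps, via lsq_linear.

    Returns (objective, g).  The minimiser of ||D g||^2 under box bounds is
    exactly a bounded-variable least-squares problem with the first
    difference matrix D and zero target.
    """
    n = f.size
    D = diags([-np.ones(n - 1), np.ones(n - 1)], [0, 1], shape=(n - 1, n)).toarray()
    res = lsq_linear(
        D, np.zeros(n - 1), bounds=(f - eps, f + eps), method="trf",
        tol=1e-14, max_iter=3000,
    )
    return 2.0 * res.cost, res.x


def oneclass_qp(Q: np.ndarray, nu: float):
    """Minimise 1/2 a'Qa s.t. sum(a) = nu*n, 0 <= a <= 1 (trust-constr)."""
    n = Q.shape[0]
    res = minimize(
        lambda a: 0.5 * a @ Q @ a,
        np.full(n, nu),
        jac=lambda a: Q @ a,
        hess=lambda a: Q,
        method="trust-constr",
        constraints=[LinearConstraint(np.ones(n), nu * n, nu * n)],
        bounds=[(0.0, 1.0)] * n,
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=5000),
    )
    return 0.5 * res.x @ Q @ res.x, res.x


def csvm_qp(H: np.ndarray, y: np.ndarray, C: float):
    """Minimise 1/2 a'Ha - 1'a s.t. y'a = 0, 0 <= a <= C (trust-constr)."""
    n = y.size
    res = minimize(
        lambda a: 0.5 * a @ H @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: H @ a - 1.0,
        hess=lambda a: H,
        method="trust-constr",
        constraints=[LinearConstraint(y, 0.0, 0.0)],
        bounds=[(0.0, C)] * n,
        options=dict(gtol=1e-12, xtol=1e-14, maxiter=5000),
    )
    return 0.5 * res.x @ H @ res.x - res.x.sum(), res.x


def random_signal(rng: np.random.Generator, n: int) -> np.ndarray:
    """A mixed bag of signal shapes for fuzzing."""
    kind = int(rng.integers(4))
    if kind == 0:
        return rng.normal(0, 1, n)
    if kind == 1:
        return np.cumsum(rng.normal(0, 0.5, n))
    if kind == 2:
        return np.sin(np.linspace(0, float(rng.uniform(1, 20)), n)) + rng.normal(0, 0.2, n)
    return rng.choice([-1.0, 0.0, 1.0, 2.0], n)
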