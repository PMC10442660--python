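"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the SVM
oracle solves the dual quadratic program directly with a generic
constrained optimiser, and the dilation oracle enumerates pixel offsets.
"""

import numpy as np
from scipy.optimize import minimize


def qp_svm_decision(X, y01, C, sigma2, Xtest):
    """Decision values of the soft-margin RBF-SVM via the dual QP.

    maximise  sum(a) - 1/2 a^T (yy^T * K) a   s.t.  0 <= a <= C, a.y = 0,
    solved with SLSQP from several starts; the bias is recovered from the
    margin support vectors.
    """
    X = np.asarray(X, float)
    y = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    n = len(X)
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / sigma2)
    Q = (y[:, None] * y[None, :]) * K

    def neg(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    best = None
    for s in range(3):
        a0 = np.full(n, C / 2) if s == 0 else np.random.default_rng(s).uniform(0, C, n)
        res = minimize(
            neg, a0, jac=grad, bounds=[(0.0, C)] * n, constraints=cons,
            method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = best.x
    ay = a * y

    def f_no_b(Z):
        Z = np.atleast_2d(Z)
        return np.exp(-((Z[:, None, :] - X[None, :, :]) ** 2).sum(-1) / sigma2) @ ay

    tol = 1e-6 * C
    margin = (a > tol) & (a < C - tol)
    b = float(np.mean(y[margin] - f_no_b(X[margin]))) if margin.any() else 0.0
    return f_no_b(Xtest) + b


def chebyshev_dilation(coords, shape, radius):
    """Set of pixels within Chebyshev distance `radius` of any coordinate,
    by direct offset enumeration."""
    out = np.zeros(shape, dtype=bool)
    for r, c in np.asarray(coords).reshape(-1, 2):
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
                    out[rr, cc] = True
    return out


def pairwise_sq_distances(X):
    """All squared Euclidean distances over i < j, by explicit loops."""
    X = np.asarray(X, float)
    out = []
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            out.append(float(((X[i] - X[j]) ** 2).sum()))
    return out
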