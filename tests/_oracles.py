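"""Independent numerical oracles used by the tests.

The closed-form output-weight solvers are checked against an iterative
quadratic minimizer (L-BFGS with the analytic gradient) of the same
objective; the oracle never calls the solvers it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def minimize_gbls_objective(
    A: np.ndarray,
    Y: np.ndarray,
    L: np.ndarray | None,
    lambda1: float,
    lambda2: float,
) -> np.ndarray:
    """Minimize ||Y-AW||^2 + lambda1 Tr((AW)^T L (AW)) + lambda2 ||W||^2."""
    A = np.asarray(A, float)
    Y = np.asarray(Y, float)
    D, C = A.shape[1], Y.shape[1]
    if L is None:
        L = np.zeros((A.shape[0], A.shape[0]))

    def fun(w):
        W = w.reshape(D, C)
        R = A @ W - Y
        Yh = A @ W
        val = np.sum(R * R) + lambda1 * np.trace(Yh.T @ L @ Yh) + lambda2 * np.sum(W * W)
        grad = 2 * (A.T @ R + lambda1 * A.T @ (L @ Yh) + lambda2 * W)
        return val, grad.ravel()

    def hessp(w, p):
        P = p.reshape(D, C)
        AP = A @ P
        H = 2 * (A.T @ AP + lambda1 * A.T @ (L @ AP) + lambda2 * P)
        return H.ravel()

    res = minimize(
        fun,
        np.zeros(D * C),
        jac=True,
        hessp=hessp,
        method="Newton-CG",
        options={"maxiter": 500, "xtol": 1e-14},
    )
    return res.x.reshape(D, C)
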