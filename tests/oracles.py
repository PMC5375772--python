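"""Independent oracles used only by the test suite.

The dual QP oracle solves the soft-margin SVM dual with scipy's SLSQP —
a generic constrained optimiser with no code shared with the package's SMO
solver — so agreement is a genuine cross-check, not a tautology.
"""

import numpy as np
from scipy.optimize import minimize

from vigileeg.svm import KernelSpec, kernel_matrix


def qp_dual_solve(X, y, C, spec: KernelSpec):
    """Maximise W(a) = sum a - 1/2 (a*y)' K (a*y) s.t. 0<=a<=C, sum a*y = 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = len(y)
    K = kernel_matrix(X, X, spec)
    Q = (y[:, None] * y[None, :]) * K

    def neg_obj(a):
        return -(np.sum(a) - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(m) - Q @ a)

    best = None
    # multistart: SLSQP is local, the QP is convex but starts help conditioning
    for a0 in (np.zeros(m), np.full(m, min(C, 1.0) / 2), np.full(m, C / 2)):
        res = minimize(
            neg_obj, a0, jac=grad, method="SLSQP",
            bounds=[(0.0, C)] * m,
            constraints=[{"type": "eq", "fun": lambda a: a @ y,
                          "jac": lambda a: y}],
            options={"maxiter": 1000, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha = np.clip(best.x, 0, C)
    return alpha, -best.fun
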