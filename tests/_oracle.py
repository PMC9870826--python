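"""Independent dense reference implementations used only by the tests.

Everything here works on explicit n x n covariance matrices and brute-force
optimisation, with no code shared with the package's sparse/MME path.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dense_restricted_ll(y, X, Z_list, variances, resid_var):
    """l_R via explicit V, log-determinants and the projection matrix."""
    n = len(y)
    V = resid_var * np.eye(n)
    for Z, v in zip(Z_list, variances):
        V += v * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + float(y @ P @ y)
    )


def dense_reml(y, X, Z_list, n_starts=4, seed=0):
    """Brute-force REML: multi-start bounded quasi-Newton plus Nelder-Mead
    polish on the nonnegative variance vector.  Returns (max l_R, variances)
    with the residual variance last."""
    k = len(Z_list) + 1
    var_y = float(np.var(y)) or 1.0
    lo = 1e-10 * var_y

    def nll(theta):
        th = np.maximum(theta, lo)
        return -dense_restricted_ll(y, X, Z_list, th[:-1], th[-1])

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = np.full(k, var_y / k) * (rng.uniform(0.2, 3.0, k) if s else 1.0)
        r = minimize(nll, x0, method="L-BFGS-B", bounds=[(lo, None)] * k)
        if best is None or r.fun < best.fun:
            best = r
    r2 = minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        options=dict(maxiter=4000, xatol=1e-11, fatol=1e-13),
    )
    if r2.fun < best.fun:
        best = r2
    theta = np.maximum(best.x, 0.0)
    theta[theta <= 2 * lo] = 0.0
    return -best.fun, theta


def dense_mme_blup(y, X, Z_list, variances, resid_var):
    """Henderson's mixed-model equations assembled densely and solved with
    one call to numpy.  Returns (fixed estimates, list of BLUP vectors)."""
    W = np.column_stack([X] + [Z for Z in Z_list])
    p = X.shape[1]
    qs = [Z.shape[1] for Z in Z_list]
    D = np.zeros(W.shape[1])
    off = p
    for q, v in zip(qs, variances):
        D[off : off + q] = 1.0 / v
        off += q
    C = W.T @ W / resid_var + np.diag(D)
    b = np.linalg.solve(C, W.T @ y / resid_var)
    out, off = [], p
    for q in qs:
        out.append(b[off : off + q])
        off += q
    return b[:p], out
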