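"""Independent numerical oracles used by the test suite.

These deliberately avoid the linear-algebra route the package itself uses:
the Gaussian likelihood is maximized by a generic numeric optimizer, and
NODF is evaluated by a literal, loop-based translation of the
decreasing-fill/overlap definition.
"""

import numpy as np
from scipy.optimize import minimize


def numeric_ml_fit(X, y, v):
    """Maximize the heteroscedastic Gaussian likelihood numerically.

    Returns (beta_hat, log_likelihood).  Two-stage optimization (BFGS then
    Nelder-Mead polish) in (beta, log sigma2) from a deliberately perturbed
    start, with no use of the normal equations.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    n = len(y)

    def nll(params):
        beta, log_s2 = params[:-1], params[-1]
        s2 = np.exp(log_s2)
        resid = y - X @ beta
        return 0.5 * (
            n * np.log(2 * np.pi * s2) + np.sum(np.log(v)) + np.sum(resid**2 / (s2 * v))
        )

    # crude but implementation-independent start: ridge-free univariate scalings
    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(max(np.var(y), 1e-4))
    stage1 = minimize(nll, x0, method="BFGS", options={"gtol": 1e-12, "maxiter": 5000})
    stage2 = minimize(
        nll,
        stage1.x,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "adaptive": True},
    )
    best = stage2 if stage2.fun <= stage1.fun else stage1
    return best.x[:-1], -best.fun


def nodf_bruteforce(binary):
    """Literal pairwise evaluation of the nestedness-by-overlap definition."""
    binary = np.asarray(binary) > 0
    total, pairs = 0.0, 0
    for mat in (binary, binary.T):
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                pairs += 1
                fill_i, fill_j = mat[i].sum(), mat[j].sum()
                if fill_i == fill_j:
                    continue
                hi, lo = (i, j) if fill_i > fill_j else (j, i)
                fill_lo = mat[lo].sum()
                if fill_lo == 0:
                    continue
                shared = int(np.sum(mat[hi] & mat[lo]))
                total += 100.0 * shared / fill_lo
    return total / pairs
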