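"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route that shares no code with
the package implementation it checks: literal rule enumeration for the
trajectory classifier, explicit normal equations for the ANCOVA, and
numerical maximum-likelihood estimation of the saturated path diagram
for the panel models.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

CUTOFFS = (12, 10, 12)


def brute_force_trajectory(w1, w2, cutoffs=CUTOFFS, threshold=0.20):
    """Literal enumeration of the trajectory rules, scale by scale."""
    above1 = [w1[i] >= cutoffs[i] for i in range(3)]
    above2 = [w2[i] >= cutoffs[i] for i in range(3)]
    high1 = above1[0] or above1[1] or above1[2]
    high2 = above2[0] or above2[1] or above2[2]
    if high1 and high2:
        return "SHR"
    if not high1 and not high2:
        return "SLR"
    if high1 and not high2:
        # every scale above its cut-off at baseline must have fallen by
        # at least the threshold fraction of its baseline total
        for i in range(3):
            if above1[i]:
                drop = w1[i] - w2[i]
                if not (w1[i] > 0 and drop / w1[i] >= threshold):
                    return "SHR"
        return "improving"
    # low -> high: every newly flagged scale must have risen by at least
    # the threshold fraction (a zero baseline counts as meaningful)
    for i in range(3):
        if above2[i]:
            if w1[i] == 0:
                continue
            rise = w2[i] - w1[i]
            if not rise / w1[i] >= threshold:
                return "SLR"
    return "deteriorating"


def normal_equations_ancova(y, X_full, X_null):
    """F test of the full against the null design via explicit RSS."""

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r), beta

    rss_full, beta_full = rss(X_full)
    rss_null, _ = rss(X_null)
    k = X_full.shape[1] - X_null.shape[1]
    df_resid = len(y) - X_full.shape[1]
    f = ((rss_null - rss_full) / k) / (rss_full / df_resid)
    return f, beta_full


def ml_sem_paths(S):
    """Maximum-likelihood estimation of the saturated two-wave path
    diagram, by direct minimisation of the normal-theory discrepancy
    F(theta) = log|Sigma(theta)| + tr(S Sigma^-1).

    ``S`` is the 4x4 sample covariance of (S1, P1, S2, P2).  Returns the
    fitted (a, b, e, f) plus the wave-1 and residual correlations
    (c, d) and the implied covariance at the optimum.
    """
    S = np.asarray(S, dtype=float)

    def implied(theta):
        a, b, e, f, v11, v22, v12, p11, p22, p12 = theta
        V1 = np.array([[v11, v12], [v12, v22]])
        Psi = np.array([[p11, p12], [p12, p22]])
        B = np.array([[a, e], [f, b]])
        C = V1 @ B.T
        return np.block([[V1, C], [C.T, B @ V1 @ B.T + Psi]])

    def discrepancy(theta):
        sigma = implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e8
        return logdet + float(np.trace(S @ np.linalg.inv(sigma)))

    x0 = np.array([0.3, 0.3, 0.0, 0.0,
                   S[0, 0], S[1, 1], S[0, 1],
                   0.6 * S[2, 2], 0.6 * S[3, 3], 0.0])
    res = minimize(discrepancy, x0, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 5000})
    res = minimize(discrepancy, res.x, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 20000, "maxfev": 20000})
    a, b, e, f, v11, v22, v12, p11, p22, p12 = res.x
    c = v12 / np.sqrt(v11 * v22)
    d = p12 / np.sqrt(p11 * p22)
    return {"a": a, "b": b, "e": e, "f": f, "c": c, "d": d,
            "implied": implied(res.x), "fun": res.fun}
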