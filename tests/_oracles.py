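"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: the ridge oracle
minimizes the penalized objective by generic numerical optimization, and the
UPGMA oracle agglomerates clusters by brute force over member pairs.
"""

import numpy as np
from itertools import combinations

from scipy.optimize import minimize


def ridge_oracle(X, Y, alpha):
    """Minimize ||Y - XW - b||^2 + alpha ||W||^2 (intercept unpenalized)
    by generic optimization. Returns (W, b)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n, k = X.shape
    r = Y.shape[1]

    def objective(theta):
        W = theta[: k * r].reshape(k, r)
        b = theta[k * r:]
        resid = Y - X @ W - b
        return float(np.sum(resid**2) + alpha * np.sum(W**2))

    def grad(theta):
        W = theta[: k * r].reshape(k, r)
        b = theta[k * r:]
        resid = Y - X @ W - b
        gW = -2 * X.T @ resid + 2 * alpha * W
        gb = -2 * resid.sum(axis=0)
        return np.concatenate([gW.ravel(), gb])

    theta0 = np.zeros(k * r + r)
    res = minimize(objective, theta0, jac=grad, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[: k * r].reshape(k, r), res.x[k * r:]


def upgma_oracle_cophenetic(rdm):
    """Brute-force UPGMA; returns the condensed cophenetic distance matrix.

    Cluster-pair distance is the arithmetic mean over all member pairs of
    the original distances; the minimal pair is merged at each step (ties:
    lexicographically smallest sorted member tuple), and every cross-cluster
    leaf pair is assigned the merge height.
    """
    rdm = np.asarray(rdm, float)
    n = rdm.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))

    def cluster_dist(a, b):
        return float(np.mean([rdm[i, j] for i in a for j in b]))

    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            d = cluster_dist(a, b)
            key = (d, tuple(sorted(a)), tuple(sorted(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = d
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)

    return coph[np.triu_indices(n, k=1)]
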