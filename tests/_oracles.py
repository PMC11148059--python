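"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain loops, independent of the
package's vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def fcm_loop(values, centroids, m, tol, max_iter):
    """Reference fuzzy C-means on scalar data, loop-by-loop.

    Returns (centroids, memberships, n_iter, converged) with memberships
    aligned to ``values``.
    """
    values = [float(v) for v in values]
    centroids = [float(c) for c in centroids]
    n, c = len(values), len(centroids)
    u = [[0.0] * c for _ in range(n)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            dists = [abs(values[i] - centroids[k]) for k in range(c)]
            if min(dists) == 0.0:
                hits = [1.0 if d == 0.0 else 0.0 for d in dists]
                s = sum(hits)
                for k in range(c):
                    u[i][k] = hits[k] / s
                continue
            for k in range(c):
                acc = 0.0
                for j in range(c):
                    acc += (dists[k] / dists[j]) ** (2.0 / (m - 1.0))
                u[i][k] = 1.0 / acc
        new_centroids = []
        for k in range(c):
            num = sum((u[i][k] ** m) * values[i] for i in range(n))
            den = sum(u[i][k] ** m for i in range(n))
            new_centroids.append(num / den)
        shift = max(abs(new_centroids[k] - centroids[k]) for k in range(c))
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    return np.array(centroids), np.array(u), it, converged


def regional_mean_loop(metric_map, labels, n_zones):
    """Per-zone mean by explicit per-pixel accumulation."""
    sums = [0.0] * (n_zones + 1)
    counts = [0] * (n_zones + 1)
    h, w = metric_map.shape
    for r in range(h):
        for c in range(w):
            z = int(labels[r, c])
            sums[z] += float(metric_map[r, c])
            counts[z] += 1
    return [sums[z] / counts[z] if counts[z] else float("nan")
            for z in range(1, n_zones + 1)]


def ols_normal_equations(X, y):
    """Closed-form least squares: beta = (XᵀX)⁻¹ Xᵀ y with an intercept."""
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def two_sample_t_power(mean1, sd1, mean2, sd2, n, alpha=0.05):
    """Analytic power of the equal-variance two-sample t-test."""
    from scipy.stats import nct, t as tdist

    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    ncp = abs(mean1 - mean2) / (pooled * np.sqrt(2.0 / n))
    df = 2 * n - 2
    tcrit = tdist.ppf(1 - alpha / 2, df)
    return float(nct.sf(tcrit, df, ncp) + nct.cdf(-tcrit, df, ncp))
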