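"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain explicit loops over the defining
formulas, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_oracle(segment: np.ndarray) -> np.ndarray:
    """Per-pair Pearson correlation by the definitional sum formula."""
    t, n = segment.shape
    w = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi = segment[:, i] - segment[:, i].mean()
            xj = segment[:, j] - segment[:, j].mean()
            denom = math.sqrt(float(xi @ xi)) * math.sqrt(float(xj @ xj))
            w[i, j] = float(xi @ xj) / denom if denom > 0 else 0.0
    return w


def temporal_variability_oracle(windows: np.ndarray) -> np.ndarray:
    """Double loop over window pairs; profile = row with self-entry removed."""
    k, n, _ = windows.shape
    v = np.zeros(n)
    for i in range(n):
        cors = []
        for a in range(k):
            for b in range(a + 1, k):
                pa = np.delete(windows[a, i, :], i)
                pb = np.delete(windows[b, i, :], i)
                pa = pa - pa.mean()
                pb = pb - pb.mean()
                denom = math.sqrt(float(pa @ pa)) * math.sqrt(float(pb @ pb))
                cors.append(float(pa @ pb) / denom if denom > 0 else 0.0)
        v[i] = 1.0 - sum(cors) / len(cors)
    return v


def subject_cluster_series_oracle(
    fc_series: np.ndarray, assignment: np.ndarray, n_clusters: int
) -> np.ndarray:
    """Explicit loop over cluster members: mean FC series per cluster."""
    k = fc_series.shape[1]
    out = np.zeros((n_clusters, k))
    for u in range(n_clusters):
        members = [p for p in range(len(assignment)) if assignment[p] == u]
        for t in range(k):
            out[u, t] = sum(fc_series[p, t] for p in members) / len(members)
    return out


def hfcn_oracle(cluster_series: np.ndarray) -> np.ndarray:
    """Pairwise Pearson of cluster-mean series, definitional loop."""
    return pearson_oracle(cluster_series.T)


def node_strength_oracle(matrix: np.ndarray) -> np.ndarray:
    """Per-row sum of absolute off-diagonal weights."""
    n = matrix.shape[0]
    d = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i] += abs(matrix[i, j])
    return d


def clustering_coefficient_oracle(matrix: np.ndarray) -> np.ndarray:
    """Onnela weighted local clustering, explicit triple loop.

    Weights are absolute values rescaled by the global maximum off-diagonal
    weight; nodes with fewer than two neighbours score 0.
    """
    n = matrix.shape[0]
    w = np.abs(np.array(matrix, dtype=float))
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    c = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if w[i, j] > 0]
        r = len(neigh)
        if r < 2:
            continue
        t = 0.0
        for j in neigh:
            for h in neigh:
                if j != h:
                    t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        c[i] = 2.0 * t / (r * (r - 1))
    return c


def kmeans_two_cluster_oracle(points: np.ndarray) -> float:
    """Minimum within-cluster sum of squares over every 2-partition."""
    n = len(points)
    best = math.inf
    for mask in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0
        a = [p for p in range(n) if not (mask >> p) & 1]
        b = [p for p in range(n) if (mask >> p) & 1]
        if not a or not b:
            continue
        wcss = 0.0
        for grp in (a, b):
            centre = points[grp].mean(axis=0)
            wcss += float(((points[grp] - centre) ** 2).sum())
        best = min(best, wcss)
    return best


def soft_threshold_oracle(beta_ols: np.ndarray, lam: float) -> np.ndarray:
    """Lasso solution on an orthonormal design: soft-thresholded OLS."""
    return np.sign(beta_ols) * np.maximum(np.abs(beta_ols) - lam, 0.0)
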