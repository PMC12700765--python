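"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive — plain loops and textbook formulas —
so it exercises none of the code paths it is used to check.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(n: int, edges) -> np.ndarray:
    """All-pairs shortest paths by repeated breadth-first search."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if np.isinf(D[s, v]):
                        D[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return D


def ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form least-squares slope."""
    xb, yb = x.mean(), y.mean()
    return float(((x - xb) * (y - yb)).sum() / ((x - xb) ** 2).sum())


def ols_se(x: np.ndarray, y: np.ndarray) -> float:
    """Classical slope standard error."""
    n = len(x)
    b = ols_slope(x, y)
    a = y.mean() - b * x.mean()
    resid = y - a - b * x
    s2 = (resid**2).sum() / (n - 2)
    return float(np.sqrt(s2 / ((x - x.mean()) ** 2).sum()))


def hc1_se(x: np.ndarray, y: np.ndarray) -> float:
    """HC1 sandwich slope standard error by the textbook formula."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ (X * (e**2)[:, None])
    cov = n / (n - 2) * bread @ meat @ bread
    return float(np.sqrt(cov[1, 1]))


def sandwich_pairsum_se(x, y, weights) -> float:
    """Slope SE from the pairwise-sum sandwich with an explicit double loop."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    e = y - X @ beta
    meat = np.zeros((2, 2))
    for i in range(n):
        for j in range(n):
            w = weights[i, j] if i != j else 1.0
            if w == 0:
                continue
            ui = X[i] * e[i]
            uj = X[j] * e[j]
            meat += w * np.outer(ui, uj)
    bread = np.linalg.inv(X.T @ X)
    cov = bread @ meat @ bread
    return float(np.sqrt(max(cov[1, 1], 0.0)))


def enumerate_dyads(y, x, adjacency):
    """All unordered pairs by a double loop."""
    n = len(y)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append((i, j, abs(y[i] - y[j]), abs(x[i] - x[j]), adjacency[i, j]))
    return rows


def complete_linkage_cophenetic(D: np.ndarray) -> np.ndarray:
    """Step-by-step complete-linkage agglomeration; returns merge heights."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = np.zeros((n, n))
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                heights[i, j] = heights[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def modularity(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a partition, direct double sum."""
    A = np.asarray(adjacency, dtype=float)
    k = A.sum(axis=1)
    two_m = A.sum()
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_two_coloring_modularity(adjacency: np.ndarray) -> float:
    """Max modularity over every 2-coloring (vectorized exhaustive scan)."""
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = A.sum()
    B = A - np.outer(k, k) / two_m
    codes = np.arange(2**n, dtype=np.int64)
    best = -np.inf
    for start in range(0, 2**n, 2**16):
        chunk = codes[start : start + 2**16]
        S = ((chunk[:, None] >> np.arange(n)) & 1).astype(float)
        q_same = np.einsum("ci,ij,cj->c", S, B, S)
        q_other = np.einsum("ci,ij,cj->c", 1 - S, B, 1 - S)
        best = max(best, float((q_same + q_other).max() / two_m))
    return best


def dense_dyadic_profile(dt, gamma: float):
    """Profile ML pieces for the dyadic mixed model with a dense covariance.

    Builds V = I + gamma * A A' explicitly (A = node incidence), then solves
    the GLS normal equations directly.  Returns (beta, q, logdet).
    """
    m, n = dt.n_dyads, dt.n_nodes
    A = np.zeros((m, n))
    A[np.arange(m), dt.node_a] = 1.0
    A[np.arange(m), dt.node_b] = 1.0
    V = np.eye(m) + gamma * A @ A.T
    Vi = np.linalg.inv(V)
    F = np.column_stack([np.ones(m), dt.x_dist, dt.z])
    beta = np.linalg.solve(F.T @ Vi @ F, F.T @ Vi @ dt.y_dist)
    r = dt.y_dist - F @ beta
    q = float(r @ Vi @ r)
    logdet = float(np.linalg.slogdet(V)[1])
    return beta, q, logdet
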