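"""Independent brute-force implementations used as test oracles.

Everything here is deliberately naive — explicit loops, Floyd-Warshall
all-pairs paths, truncated matrix-exponential series — and shares no code
with the package's metric implementations.  Partition-dependent
quantities (modularity, participation, within-module degree z, diversity)
take the partition as an argument and verify the formula, not the
community search.
"""

from __future__ import annotations

import math

import numpy as np

INF = float("inf")


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths; 0 off-diagonal means 'no edge'."""
    n = lengths.shape[0]
    d = np.full((n, n), INF)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_from_lengths(lengths: np.ndarray) -> float:
    d = floyd_warshall(lengths)
    n = d.shape[0]
    if n < 2:
        return 0.0
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i, j] < INF:
                tot += 1.0 / d[i, j]
    return tot / (n * (n - 1))


def weighted_lengths(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    L = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                L[i, j] = 1.0 / W[i, j]
    return L


def binary_lengths(B: np.ndarray) -> np.ndarray:
    return (B != 0).astype(float)


def clustering_weighted(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering, weights normalized by the maximum."""
    n = W.shape[0]
    wmax = W.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    s += ((W[i, j] / wmax) * (W[j, h] / wmax) * (W[i, h] / wmax)) ** (1 / 3)
        out[i] = s / (k * (k - 1))
    return out


def clustering_binary(B: np.ndarray) -> np.ndarray:
    n = B.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if B[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = 0
        for j in nbrs:
            for h in nbrs:
                if j < h and B[j, h]:
                    tri += 1
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def transitivity_weighted(W: np.ndarray) -> float:
    n = W.shape[0]
    wmax = W.max()
    if wmax == 0:
        return 0.0
    num = 0.0
    den = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if W[i, j] > 0)
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    num += ((W[i, j] / wmax) * (W[j, h] / wmax) * (W[i, h] / wmax)) ** (1 / 3)
    return num / den if den else 0.0


def char_path_length(W: np.ndarray) -> float:
    d = floyd_warshall(weighted_lengths(W))
    vals = [d[i, j] for i in range(len(d)) for j in range(i + 1, len(d)) if d[i, j] < INF]
    return float(np.mean(vals))


def closeness_weighted(W: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weighted_lengths(W))
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        reach = [d[i, j] for j in range(n) if j != i and d[i, j] < INF]
        if reach and sum(reach) > 0:
            r = len(reach)
            out[i] = (r / sum(reach)) * (r / (n - 1))
    return out


def local_efficiency_weighted(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = efficiency_from_lengths(weighted_lengths(sub))
    return out


def betweenness_weighted(W: np.ndarray) -> np.ndarray:
    """Betweenness by explicit shortest-path counting over a Floyd table.

    Path counts come from the recurrence sigma[i][j] = sum of sigma over
    predecessors; with continuous weights ties are measure-zero, so the
    tolerance comparison is safe on random matrices.
    """
    n = W.shape[0]
    L = weighted_lengths(W)
    d = floyd_warshall(L)
    eps = 1e-12
    # count shortest paths by DP over nodes sorted by distance from source
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or d[s, t] == INF:
                continue
            tot = 0.0
            for p in range(n):
                if p != t and L[p, t] > 0 and abs(d[s, p] + L[p, t] - d[s, t]) < eps:
                    tot += sigma[s, p]
            sigma[s, t] = tot
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if s == v or t == v or d[s, t] == INF or sigma[s, t] == 0:
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) < eps:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    if n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)
    return bc


def eigenvector_centrality(W: np.ndarray, iters: int = 5000) -> np.ndarray:
    n = W.shape[0]
    v = np.ones(n) / math.sqrt(n)
    for _ in range(iters):
        nv = W @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros(n)
        nv = nv / norm
        if np.allclose(nv, v, atol=1e-14):
            break
        v = nv
    return np.abs(v)


def subgraph_centrality(W: np.ndarray, terms: int = 60) -> np.ndarray:
    n = W.shape[0]
    acc = np.eye(n)
    power = np.eye(n)
    for k in range(1, terms):
        power = power @ W / k
        acc = acc + power
    return np.diag(acc).copy()


def modularity(adj: np.ndarray, partition: list[set]) -> float:
    """Newman modularity by the explicit double sum."""
    m2 = adj.sum()  # 2m for an undirected matrix
    if m2 == 0:
        return 0.0
    k = adj.sum(axis=0)
    label = {}
    for c, comm in enumerate(partition):
        for i in comm:
            label[i] = c
    q = 0.0
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if label[i] == label[j]:
                q += adj[i, j] - k[i] * k[j] / m2
    return q / m2


def participation(W: np.ndarray, partition: list[set]) -> np.ndarray:
    n = W.shape[0]
    label = {}
    for c, comm in enumerate(partition):
        for i in comm:
            label[i] = c
    out = np.zeros(n)
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            continue
        acc = 0.0
        for c in range(len(partition)):
            kappa = sum(W[i, j] for j in range(n) if label[j] == c)
            acc += (kappa / k) ** 2
        out[i] = 1.0 - acc
    return out


def within_module_z(W: np.ndarray, partition: list[set]) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for comm in partition:
        members = sorted(comm)
        if len(members) < 2:
            continue
        kappa = [sum(W[i, j] for j in members if j != i) for i in members]
        mu = float(np.mean(kappa))
        sd = float(np.std(kappa))
        if sd > 0:
            for i, kap in zip(members, kappa):
                out[i] = (kap - mu) / sd
    return out


def diversity(W: np.ndarray, partition: list[set]) -> np.ndarray:
    n = W.shape[0]
    m = len(partition)
    out = np.zeros(n)
    if m < 2:
        return out
    label = {}
    for c, comm in enumerate(partition):
        for i in comm:
            label[i] = c
    for i in range(n):
        k = W[i].sum()
        if k == 0:
            continue
        h = 0.0
        for c in range(m):
            p = sum(W[i, j] for j in range(n) if label[j] == c) / k
            if p > 0:
                h -= p * math.log(p)
        out[i] = h / math.log(m)
    return out


def assortativity_weighted(z: np.ndarray) -> float:
    """Weighted Pearson correlation of endpoint signed strengths over edges."""
    n = z.shape[0]
    s = z.sum(axis=0)
    xs, ys, ws = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            w = abs(z[i, j])
            if w > 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
                ws += [w, w]
    ws = np.array(ws) / np.sum(ws)
    xs, ys = np.array(xs), np.array(ys)
    mx, my = ws @ xs, ws @ ys
    cov = ws @ ((xs - mx) * (ys - my))
    vx = ws @ ((xs - mx) ** 2)
    vy = ws @ ((ys - my) ** 2)
    return cov / math.sqrt(vx * vy)


def degree_assortativity(B: np.ndarray) -> float:
    n = B.shape[0]
    deg = B.sum(axis=0)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if B[i, j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    xs, ys = np.array(xs, dtype=float), np.array(ys, dtype=float)
    return float(np.corrcoef(xs, ys)[0, 1])


def coreness(B: np.ndarray) -> np.ndarray:
    """k-core numbers by iterative peeling."""
    n = B.shape[0]
    alive = [True] * n
    deg = list(B.sum(axis=0))
    core = [0] * n
    k = 0
    remaining = n
    while remaining:
        k += 1
        changed = True
        while changed:
            changed = False
            for i in range(n):
                if alive[i] and deg[i] < k:
                    core[i] = k - 1
                    alive[i] = False
                    remaining -= 1
                    changed = True
                    for j in range(n):
                        if B[i, j] and alive[j]:
                            deg[j] -= 1
    return np.array(core, dtype=float)


def rich_club(B: np.ndarray) -> float:
    deg = B.sum(axis=0)
    k_med = float(np.median(deg))
    rich = [i for i in range(B.shape[0]) if deg[i] > k_med]
    if len(rich) < 2:
        return 0.0
    edges = sum(B[i, j] for i in rich for j in rich if i != j)
    return edges / (len(rich) * (len(rich) - 1))


def resilience_slope(degrees: np.ndarray, n_bins: int = 10) -> float:
    """Log-log degree-distribution slope via explicit normal equations."""
    deg = np.asarray(degrees, dtype=float)
    deg = deg[deg > 0]
    lo, hi = deg.min(), deg.max()
    edges = [lo * (hi / lo) ** (k / n_bins) for k in range(n_bins + 1)]
    xs, ys = [], []
    for b in range(n_bins):
        top_inclusive = b == n_bins - 1
        cnt = sum(
            1
            for d in deg
            if (edges[b] <= d < edges[b + 1]) or (top_inclusive and d == edges[b + 1])
        )
        if cnt > 0:
            center = math.sqrt(edges[b] * edges[b + 1])
            xs.append(math.log(center))
            ys.append(math.log(cnt / (edges[b + 1] - edges[b])))
    if len(xs) < 3:
        raise ValueError("fewer than 3 non-empty bins")
    xs, ys = np.array(xs), np.array(ys)
    xbar, ybar = xs.mean(), ys.mean()
    return float(((xs - xbar) @ (ys - ybar)) / ((xs - xbar) @ (xs - xbar)))


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, intercept) by explicit normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def glm_group_f(y, group, covars) -> tuple[float, float]:
    """F and two-sided p for the group indicator via explicit matrices."""
    from scipy import stats as sps

    n = len(y)
    X = np.column_stack([np.ones(n), group] + list(covars))
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    f = (beta[1] / se) ** 2
    return float(f), float(sps.f.sf(f, 1, dof))


def partial_corr(y, x, c) -> float:
    """Partial correlation by double residualization with explicit OLS."""
    sy, iy = ols_fit(np.asarray(c, float), np.asarray(y, float))
    sx, ix = ols_fit(np.asarray(c, float), np.asarray(x, float))
    ry = np.asarray(y, float) - (iy + sy * np.asarray(c, float))
    rx = np.asarray(x, float) - (ix + sx * np.asarray(c, float))
    return float(np.corrcoef(ry, rx)[0, 1])
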