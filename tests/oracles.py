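"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over the defining formulas, on
purpose: these functions must stay independent of the code paths they check.
"""

from __future__ import annotations

import heapq
import math

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------- #
# statistics
# --------------------------------------------------------------------------- #


def icc31_anova(x1, x2, alpha=0.05):
    """ICC(3,1) + CI from literal two-way ANOVA sums of squares."""
    x1 = list(map(float, x1))
    x2 = list(map(float, x2))
    n, k = len(x1), 2
    grand = sum(x1 + x2) / (n * k)
    ss_subj = sum(k * ((a + b) / 2 - grand) ** 2 for a, b in zip(x1, x2))
    m1 = sum(x1) / n
    m2 = sum(x2) / n
    ss_sess = n * ((m1 - grand) ** 2 + (m2 - grand) ** 2)
    ss_tot = sum((v - grand) ** 2 for v in x1 + x2)
    ss_err = ss_tot - ss_subj - ss_sess
    df1, df2 = n - 1, (n - 1) * (k - 1)
    bms = ss_subj / df1
    ems = ss_err / df2
    icc = (bms - ems) / (bms + (k - 1) * ems)
    f = bms / ems
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return icc, lo, hi, f


def pearson_matrix(signals):
    """Textbook covariance-formula Pearson matrix (diagonal kept at 1)."""
    t, n = signals.shape
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            xi = signals[:, i] - signals[:, i].mean()
            xj = signals[:, j] - signals[:, j].mean()
            out[i, j] = (xi * xj).sum() / math.sqrt((xi**2).sum() * (xj**2).sum())
    return out


# --------------------------------------------------------------------------- #
# graph metrics (z: N x N with NaN for missing, symmetric, diag NaN)
# --------------------------------------------------------------------------- #


def _finite_pairs(z):
    n = z.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if np.isfinite(z[i, j]):
                yield i, j, z[i, j]


def pair_mean_within(z, labels):
    vals = [w for i, j, w in _finite_pairs(z) if labels[i] == labels[j]]
    return float(np.mean(vals)) if vals else float("nan")


def pair_mean_between(z, labels):
    vals = [w for i, j, w in _finite_pairs(z) if labels[i] != labels[j]]
    return float(np.mean(vals)) if vals else float("nan")


def strength(z):
    n = z.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(z[i, j]):
                out[i] += z[i, j]
    return out


def degree_count(z, tau):
    n = z.shape[0]
    out = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(z[i, j]) and z[i, j] > tau:
                out[i] += 1
    return out


def edge_density(z, tau):
    n = z.shape[0]
    count = sum(1 for i, j, w in _finite_pairs(z) if w > tau)
    return count / (n * (n - 1) / 2)


def onnela_clustering(z):
    """Exhaustive triple-loop Onnela clustering (weights / max weight)."""
    n = z.shape[0]
    w = np.where(np.isfinite(z), z, 0.0)
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    what = w / wmax
    c = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    acc += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = acc / (k * (k - 1))
    return c


def newman_modularity(z, labels):
    """Double-loop Newman Q on the missing-as-zero weight matrix."""
    n = z.shape[0]
    w = np.where(np.isfinite(z), z, 0.0)
    np.fill_diagonal(w, 0.0)
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def dijkstra_cpl(z):
    """Hand Dijkstra over 1/z edge lengths; mean finite pair distance."""
    n = z.shape[0]
    w = np.where(np.isfinite(z), z, 0.0)
    np.fill_diagonal(w, 0.0)
    adj = [
        [(j, 1.0 / w[i, j]) for j in range(n) if w[i, j] > 0] for i in range(n)
    ]
    dists = []
    for src in range(n):
        dist = [math.inf] * n
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, length in adj[u]:
                nd = d + length
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j in range(src + 1, n):
            if math.isfinite(dist[j]):
                dists.append(dist[j])
    return float(np.mean(dists)) if dists else float("nan")


def power_iteration_centrality(z, iters=20000, tol=1e-14):
    """Dominant eigenvector by plain power iteration, unit norm, nonneg."""
    w = np.where(np.isfinite(z), z, 0.0)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    v = np.ones(n) / math.sqrt(n)
    for _ in range(iters):
        nxt = w @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            return v
        nxt /= norm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    if v.sum() < 0:
        v = -v
    return np.clip(v, 0.0, None) / np.linalg.norm(np.clip(v, 0.0, None))


# --------------------------------------------------------------------------- #
# random test matrices
# --------------------------------------------------------------------------- #


def random_z_matrix(rng, n_nodes, missing_frac=0.15):
    """Random symmetric nonnegative z matrix with NaN diagonal and holes.

    Every node keeps at least one finite edge so that implementation and
    oracle agree on the node set.
    """
    z = rng.uniform(0.05, 1.2, size=(n_nodes, n_nodes))
    z = (z + z.T) / 2.0
    holes = rng.random((n_nodes, n_nodes)) < missing_frac
    holes = holes | holes.T
    z[holes] = np.nan
    np.fill_diagonal(z, np.nan)
    for i in range(n_nodes):
        off = [j for j in range(n_nodes) if j != i]
        if not any(np.isfinite(z[i, j]) for j in off):
            j = int(rng.choice(off))
            z[i, j] = z[j, i] = rng.uniform(0.05, 1.2)
    return z
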