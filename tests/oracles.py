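"""Independent brute-force oracles, written straight from the published
formulas, used to pin down the vectorized implementations."""

import math

import numpy as np


def filter_oracle(counts, lib_sizes, min_cpm, min_frac):
    """Hand-coded cpm filter: loop over genes and samples."""
    n = counts.shape[1]
    need = math.ceil(min_frac * n)
    keep = []
    for g in range(counts.shape[0]):
        n_ok = sum(1 for k in range(n)
                   if counts[g, k] / lib_sizes[k] * 1e6 >= min_cpm)
        keep.append(n_ok >= need)
    return np.array(keep)


def tmm_oracle(counts, ref, k, trim_m=0.30, trim_a=0.05):
    """Step-by-step trimmed mean of M-values for sample k against ref:
    explicit M/A/weight lists, sort-and-slice double trimming, weighted mean."""
    counts = np.asarray(counts, float)
    n_k = counts[:, k].sum()
    n_r = counts[:, ref].sum()
    entries = []
    for g in range(counts.shape[0]):
        y_k, y_r = counts[g, k], counts[g, ref]
        if y_k <= 0 or y_r <= 0:
            continue
        p_k, p_r = y_k / n_k, y_r / n_r
        m = math.log2(p_k / p_r)
        a = 0.5 * math.log2(p_k * p_r)
        w = (n_k - y_k) / (n_k * y_k) + (n_r - y_r) / (n_r * y_r)
        entries.append((m, a, w))
    n = len(entries)
    by_m = sorted(range(n), key=lambda i: (entries[i][0], i))
    by_a = sorted(range(n), key=lambda i: (entries[i][1], i))
    lo_m = math.floor(n * trim_m)
    lo_a = math.floor(n * trim_a)
    keep_m = set(by_m[lo_m:n - lo_m])
    keep_a = set(by_a[lo_a:n - lo_a])
    keep = keep_m & keep_a
    num = sum(entries[i][0] / entries[i][2] for i in keep)
    den = sum(1.0 / entries[i][2] for i in keep)
    return 2.0 ** (num / den)


def tom_oracle(adjacency):
    """Triple-loop topological overlap."""
    a = np.asarray(adjacency, float)
    n = a.shape[0]
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def power_iteration_eigengene(expr, n_iter=5000, tol=1e-14):
    """First PC of z-scored expression via power iteration on the sample
    covariance of the standardized genes."""
    expr = np.asarray(expr, float)
    z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, keepdims=True)
    c = z.T @ z                      # samples x samples
    v = np.ones(c.shape[0]) / np.sqrt(c.shape[0])
    for _ in range(n_iter):
        nv = c @ v
        nv /= np.linalg.norm(nv)
        if np.linalg.norm(nv - v) < tol and _ > 10:
            v = nv
            break
        v = nv
    lam = float(v @ c @ v)
    total = float(np.trace(c))
    # orient: mean correlation of genes with the eigengene non-negative
    corr = np.array([np.corrcoef(z[g], v)[0, 1] for g in range(z.shape[0])])
    if corr.mean() < 0:
        v = -v
    return v, lam / total


def bh_oracle(p):
    """Hand step-up: sort, multiply by m/rank, enforce monotonicity from the
    largest down, clip at 1, undo the sort."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top, 1.0)
        adj[i] = val
        prev = val
    return np.array(adj)


def csv_oracle(labels, native_edges, foreign_edges):
    """Pair enumeration of the relative community-structure validation index."""
    n = len(labels)
    n_native = n_both = 0
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] != labels[j] or labels[i] == "grey":
                continue
            if native_edges[i, j]:
                n_native += 1
                if foreign_edges[i, j]:
                    n_both += 1
    return 100.0 * n_both / n_native if n_native else float("nan")


def wls_oracle(y, w, X):
    """Per-gene weighted least squares by explicit normal equations."""
    betas, s2s = [], []
    n, p = X.shape
    for g in range(y.shape[0]):
        W = np.diag(w[g])
        A = X.T @ W @ X
        b = X.T @ W @ y[g]
        beta = np.linalg.solve(A, b)
        r = y[g] - X @ beta
        s2s.append(float(r @ W @ r) / (n - p))
        betas.append(beta)
    return np.array(betas), np.array(s2s)


def jaccard_overlap_oracle(set_a, set_b):
    inter = len(set_a & set_b)
    return inter / len(set_a | set_b), inter / min(len(set_a), len(set_b))
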