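"""Independent brute-force / reference implementations used as test oracles.

Everything here is deliberately written from the textbook definitions, with
plain loops, sharing no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np


def fcm_reference(X: np.ndarray, k: int, m: float, seed: int, tol: float = 1e-12, max_iter: int = 500) -> float:
    """One random-initialisation fuzzy c-means run; returns the final objective."""
    rng = np.random.default_rng(seed)
    C = X[rng.choice(len(X), size=k, replace=False)].astype(float).copy()

    def memberships(C):
        U = np.zeros((len(X), k))
        for i in range(len(X)):
            d2 = np.array([float(((X[i] - C[c]) ** 2).sum()) for c in range(k)])
            hit = d2 < 1e-300
            if hit.any():
                U[i] = hit / hit.sum()
            else:
                inv = (1.0 / d2) ** (1.0 / (m - 1.0))
                U[i] = inv / inv.sum()
        return U

    def objective(C, U):
        tot = 0.0
        for i in range(len(X)):
            for c in range(k):
                tot += (U[i, c] ** m) * float(((X[i] - C[c]) ** 2).sum())
        return tot

    prev = np.inf
    for _ in range(max_iter):
        U = memberships(C)
        Um = U**m
        C = (Um.T @ X) / Um.sum(axis=0)[:, None]
        obj = objective(C, memberships(C))
        if prev - obj < tol:
            break
        prev = obj
    return objective(C, memberships(C))


def best_fcm_objective(X: np.ndarray, k: int, m: float, n_restarts: int = 200, seed: int = 0) -> float:
    return min(fcm_reference(X, k, m, seed=seed + r) for r in range(n_restarts))


def kmeans_reference_sse(X: np.ndarray, k: int, seed: int, max_iter: int = 200) -> tuple[np.ndarray, float]:
    """One Lloyd k-means run from random distinct points; (labels, SSE)."""
    rng = np.random.default_rng(seed)
    C = X[rng.choice(len(X), size=k, replace=False)].astype(float).copy()
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        new = np.array([int(np.argmin([((x - c) ** 2).sum() for c in C])) for x in X])
        for c in range(k):
            if (new == c).any():
                C[c] = X[new == c].mean(axis=0)
        if (new == labels).all():
            break
        labels = new
    sse = sum(float(((X[i] - C[labels[i]]) ** 2).sum()) for i in range(len(X)))
    return labels, sse


def best_kmeans_sse(X: np.ndarray, k: int, n_restarts: int = 500, seed: int = 0) -> float:
    return min(kmeans_reference_sse(X, k, seed + r)[1] for r in range(n_restarts))


def exhaustive_best_2partition(X: np.ndarray) -> frozenset:
    """Exact minimum within-cluster-SSE 2-partition (indices of one side)."""
    n = len(X)
    best_sse, best_set = np.inf, None
    for mask in range(1, 2 ** (n - 1)):  # index 0 stays on side B: halves the search
        side = [i for i in range(1, n) if mask & (1 << (i - 1))]
        other = [i for i in range(n) if i not in side]
        if not side or not other:
            continue
        sse = 0.0
        for group in (side, other):
            centre = X[group].mean(axis=0)
            sse += sum(float(((X[i] - centre) ** 2).sum()) for i in group)
        if sse < best_sse:
            best_sse, best_set = sse, frozenset(side)
    return best_set


def prune_reference(edges, tss_rows, tfbs_rows, de_genes, tf_list, up=400, down=300, ignore_strand=False):
    """All-pairs interval scan: the retained (regulator, target) set."""
    de, tfs = set(de_genes), set(tf_list)
    tss_of = {}
    for row in tss_rows.itertuples(index=False):
        tss_of.setdefault(row.gene, (row.chrom, int(row.tss), row.strand))
    retained = set()
    for erow in edges.itertuples(index=False):
        r, t = erow.regulator, erow.target
        if r not in tfs or t not in de or t not in tss_of:
            continue
        chrom, pos, strand = tss_of[t]
        if strand == "+" or ignore_strand:
            w0, w1 = pos - up, pos + down
        else:
            w0, w1 = pos - down, pos + up
        w0, w1 = max(w0, 0), max(w1, 0)
        for srow in tfbs_rows.itertuples(index=False):
            if srow.tf == r and srow.chrom == chrom and max(int(srow.start), w0) < min(int(srow.end), w1):
                retained.add((r, t))
                break
    return retained


def mann_whitney_u(a, b) -> float:
    """Brute-force U statistic of sample a vs b (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else 0.5 if x == y else 0.0
    return u


def logrank_table(times_a, times_b):
    """Hand-style per-event-time O/E/V rows (all events observed, no ties across groups assumed handled)."""
    times = sorted(set(list(times_a) + list(times_b)))
    rows = []
    for t in times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x in times_a if x == t)
        d_b = sum(1 for x in times_b if x == t)
        n, d = n_a + n_b, d_a + d_b
        if d == 0:
            continue
        e = d * n_a / n
        v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1) if n > 1 else 0.0
        rows.append((t, d_a, e, v))
    return rows
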