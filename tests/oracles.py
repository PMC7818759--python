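"""Independent brute-force oracles for the weighted network measures.

Deliberately naive: explicit loops, Floyd-Warshall relaxation, exhaustive
triple enumeration.  These share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/w; inf when disconnected."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def strength(weights: np.ndarray) -> np.ndarray:
    return np.array([sum(weights[i, j] for j in range(weights.shape[0]))
                     for i in range(weights.shape[0])])


def char_path_length(dist: np.ndarray) -> float:
    n = dist.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(dist[i, j])]
    return float(np.mean(vals))


def global_eff(dist: np.ndarray) -> float:
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def clustering(weights: np.ndarray, degree_mode: str = "binary") -> np.ndarray:
    """Exhaustive enumeration over ordered neighbour pairs."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for m in range(n):
                if j != i and m != i and j != m:
                    prod = weights[i, j] * weights[i, m] * weights[j, m]
                    num += np.sign(prod) * abs(prod) ** (1.0 / 3.0)
        if degree_mode == "binary":
            k = sum(1 for j in range(n) if j != i and weights[i, j] != 0)
        else:
            k = sum(weights[i, j] for j in range(n))
        denom = k * (k - 1)
        out[i] = num / denom if denom > 1e-12 else 0.0
    return out


def local_eff(weights: np.ndarray, degree_mode: str = "binary") -> np.ndarray:
    """Neighbourhood-subgraph efficiency via explicit subgraph + Floyd-Warshall."""
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if j != i and weights[i, j] > 0]
        if len(neigh) < 2:
            continue
        sub = weights[np.ix_(neigh, neigh)]
        d = floyd_warshall(sub)
        total = 0.0
        for a, j in enumerate(neigh):
            for b, m in enumerate(neigh):
                if a == b or not np.isfinite(d[a, b]) or d[a, b] <= 0:
                    continue
                total += (weights[i, j] * weights[i, m] / d[a, b]) ** (1.0 / 3.0)
        if degree_mode == "binary":
            k = len(neigh)
        else:
            k = sum(weights[i, j] for j in range(n))
        denom = k * (k - 1)
        if denom > 1e-12:
            out[i] = 0.5 * total / denom
    return out


def bh_stepup(p_values: np.ndarray, q: float) -> np.ndarray:
    """Exhaustive Benjamini-Hochberg: largest k with p_(k) <= k q / m."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject
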