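"""Independent brute-force oracles for the test suite.

Everything here works by exhaustive enumeration (simple paths, triangles,
label permutations) so that it shares no code path with the library's
matrix-algebra / Dijkstra / Brandes implementations.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def _all_simple_paths(adj: np.ndarray, src: int, dst: int):
    """Yield every simple path src -> dst as a node tuple (enumeration)."""
    n = adj.shape[0]

    def extend(path, visited):
        last = path[-1]
        if last == dst:
            yield tuple(path)
            return
        for nxt in range(n):
            if adj[last, nxt] > 0 and nxt not in visited:
                yield from extend(path + [nxt], visited | {nxt})

    yield from extend([src], {src})


def _shortest_paths(adj: np.ndarray, lengths: np.ndarray, src: int, dst: int):
    """All minimum-length simple paths and the minimum length (inf if none)."""
    best = np.inf
    paths = []
    for path in _all_simple_paths(adj, src, dst):
        d = sum(lengths[path[t], path[t + 1]] for t in range(len(path) - 1))
        if d < best - 1e-12:
            best, paths = d, [path]
        elif abs(d - best) <= 1e-12:
            paths.append(path)
    return paths, best


def oracle_degree(w: np.ndarray, weighted: bool) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                out[i] += w[i, j] if weighted else 1.0
    return out


def oracle_clustering(w: np.ndarray, weighted: bool) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max() if w.max() > 0 else 1.0
    wt = w / wmax
    out = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if j != i and w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) == 3 and w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    total += (wt[i, j] * wt[i, h] * wt[j, h]) ** (1 / 3) if weighted else 1.0
        out[i] = total / (k * (k - 1))
    return out


def oracle_local_efficiency(w: np.ndarray, weighted: bool) -> np.ndarray:
    n = w.shape[0]
    wmax = w.max() if w.max() > 0 else 1.0
    wt = w / wmax if weighted else (w > 0).astype(float)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = wt[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, (1.0 / np.where(sub > 0, sub, 1.0)) ** (1 / 3), np.inf)
        total = 0.0
        for a, b in permutations(range(k), 2):
            _, dist = _shortest_paths(sub, lengths, a, b)
            if np.isfinite(dist) and dist > 0:
                total += (wt[i, nbrs[a]] * wt[i, nbrs[b]]) ** (1 / 3) / dist
        out[i] = total / (k * (k - 1))
    return out


def oracle_betweenness(w: np.ndarray, weighted: bool) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    if n < 3:
        return out
    with np.errstate(divide="ignore"):
        lengths = (np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
                   if weighted else np.where(w > 0, 1.0, np.inf))
    for h, j in combinations(range(n), 2):
        paths, dist = _shortest_paths(w, lengths, h, j)
        if not np.isfinite(dist) or not paths:
            continue
        rho = len(paths)
        for i in range(n):
            if i in (h, j):
                continue
            rho_i = sum(1 for p in paths if i in p)
            out[i] += 2.0 * rho_i / rho        # ordered pairs count both ways
    return out / ((n - 1) * (n - 2))


def oracle_mannwhitney_p(a, b) -> float:
    """Exact two-sided rank-sum p by complete enumeration of group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, m = a.size, b.size

    def u_stat(sample_a, sample_b):
        return sum(float(x > y) + 0.5 * float(x == y)
                   for x in sample_a for y in sample_b)

    u_obs = u_stat(a, b)
    center = n * m / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        mask = np.zeros(n + m, bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total
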