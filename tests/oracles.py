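"""Independent brute-force oracles used only by the test suite.

Everything here deliberately avoids the code paths (and, where possible,
the libraries) used by the implementation: distances come from a numpy
Floyd-Warshall, shortest paths are enumerated explicitly by DFS, the
eigenvector comes from a dense eigendecomposition, the hypergeometric tail
is summed with exact integer binomials, and the decision rule is re-derived
from scratch from score maps.
"""

from __future__ import annotations

from math import comb

import numpy as np

INF = 10**9


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    """All-pairs hop distances from a 0/1 adjacency matrix."""
    n = a.shape[0]
    d = np.where(a > 0, 1, INF).astype(np.int64)
    np.fill_diagonal(d, 0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def _enumerate_shortest_paths(a, d, u, v):
    """All shortest u-v paths as node tuples, by DFS down the distance field."""
    if d[u, v] >= INF:
        return []
    paths = []

    def walk(node, acc):
        if node == v:
            paths.append(tuple(acc))
            return
        for w in range(a.shape[0]):
            if a[node, w] and d[w, v] == d[node, v] - 1:
                walk(w, acc + [w])

    walk(u, [u])
    return paths


def brute_degree_centrality(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1) / (a.shape[0] - 1)


def brute_betweenness_centrality(a: np.ndarray) -> np.ndarray:
    """Ordered-pair betweenness by explicit shortest-path enumeration."""
    n = a.shape[0]
    d = floyd_warshall(a)
    b = np.zeros(n)
    for u in range(n):
        for v in range(n):
            if u == v or d[u, v] >= INF:
                continue
            paths = _enumerate_shortest_paths(a, d, u, v)
            sigma = len(paths)
            for i in range(n):
                if i in (u, v):
                    continue
                through = sum(1 for p in paths if i in p[1:-1])
                b[i] += through / sigma
    return b / ((n - 1) * (n - 2))


def brute_closeness_centrality(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = floyd_warshall(a)
    c = np.zeros(n)
    for i in range(n):
        reach = [j for j in range(n) if d[i, j] < INF]
        if len(reach) <= 1:
            continue
        total = sum(int(d[i, j]) for j in reach)
        c[i] = (len(reach) - 1) ** 2 / ((n - 1) * total)
    return c


def brute_eigenvector_centrality(a: np.ndarray) -> np.ndarray:
    """Perron vector from a dense symmetric eigendecomposition."""
    w, vecs = np.linalg.eigh(a.astype(float))
    x = vecs[:, int(np.argmax(w))]
    if x.sum() < 0:
        x = -x
    x = np.where(np.abs(x) < 1e-12, 0.0, x)
    return x / np.linalg.norm(x)


def fisher_upper_tail(n_t: int, n_plus: int, n_f: int, n_minus: int) -> float:
    """Exact one-sided enrichment p by summing the hypergeometric tail."""
    total = n_plus + n_minus
    drawn = n_t + n_f
    denom = comb(total, drawn)
    top = min(n_plus, drawn)
    return sum(
        comb(n_plus, k) * comb(n_minus, drawn - k) for k in range(n_t, top + 1)
    ) / denom


def brute_sgii_calls(degrees, centrality_scores, gic_scores, z, k, t, subset):
    """Re-derive the degree-gated rule from raw score maps.

    degrees: id -> raw degree; centrality_scores: measure name -> (id ->
    value); gic_scores: id -> value. Returns id -> bool.
    """
    ids = sorted(gic_scores)
    n = len(ids)

    def ranks(scores):
        order = sorted(ids, key=lambda v: (-scores[v], v))
        return {v: i + 1 for i, v in enumerate(order)}

    measure_ranks = {m: ranks(centrality_scores[m]) for m in centrality_scores}
    gic_ranks = ranks(gic_scores)
    out = {}
    for v in ids:
        if subset and degrees[v] >= z:
            out[v] = all(measure_ranks[m][v] / n < k / 100 for m in subset)
        else:
            out[v] = gic_ranks[v] / n < t / 100
    return out
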