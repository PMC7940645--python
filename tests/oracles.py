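"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by enumeration or a textbook formula,
sharing no code with the implementation it checks.
"""

from itertools import combinations, permutations

import numpy as np


def mst_total_exhaustive(d: np.ndarray) -> float:
    """Minimum spanning-tree total weight by enumerating all edge subsets
    of size n-1 and keeping the acyclic spanning ones (n <= 7 or so)."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        acyclic = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                acyclic = False
                break
            parent[ri] = rj
        if acyclic:
            best = min(best, sum(d[i, j] for i, j in subset))
    return best


def minimax_path_exhaustive(d: np.ndarray, a: int, b: int) -> float:
    """Single-linkage distance by enumerating every simple path a -> b
    and minimising the maximum edge weight along the path."""
    n = d.shape[0]
    others = [k for k in range(n) if k not in (a, b)]
    best = np.inf
    for k in range(len(others) + 1):
        for mid in permutations(others, k):
            path = (a, *mid, b)
            bottleneck = max(d[u, v] for u, v in zip(path[:-1], path[1:]))
            best = min(best, bottleneck)
    return best


def component_count_at(d: np.ndarray, lam: float) -> int:
    """Connected components of the graph {(i,j): d_ij <= lam} by an
    independent union-find."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= lam:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the textbook triple loop.

    ``lengths`` has 0 for absent edges (and the diagonal)."""
    n = lengths.shape[0]
    sp = np.full((n, n), np.inf)
    np.fill_diagonal(sp, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                sp[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                via = sp[i, k] + sp[k, j]
                if via < sp[i, j]:
                    sp[i, j] = via
    return sp


def pearson_naive(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass covariance formula."""
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
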