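"""Independent reference implementations used only to check the package.

These deliberately use different algorithms and arithmetic (exact
fractions, exhaustive enumeration, least-squares scoring of all tree
topologies) from the library code they validate.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

# exact per-symbol state contributions over (A, C, G, T, E)
_ORACLE_SHARES: dict[str, dict[str, Fraction]] = {}
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}
for sym, bases in _IUPAC.items():
    _ORACLE_SHARES[sym] = {b: Fraction(1, len(bases)) for b in bases}
for sym in ("-", "N"):
    _ORACLE_SHARES[sym] = {s: Fraction(1, 5) for s in "ACGTE"}


def entropy_oracle(column: list[str]) -> float:
    """Exact-fraction accumulation of per-cell contributions, then -sum p ln p."""
    totals = {s: Fraction(0) for s in "ACGTE"}
    for sym in column:
        for state, share in _ORACLE_SHARES[sym].items():
            totals[state] += share
    depth = len(column)
    acc = 0.0
    for state in "ACGTE":
        p = totals[state] / depth
        if p > 0:
            acc -= float(p) * math.log(float(p))
    return acc


def rarefaction_variance(counts: np.ndarray, n: int) -> float:
    """Exact hypergeometric variance of the species count in a subsample.

    Var(S_n) = sum_i q_i (1 - q_i) + 2 sum_{i<j} (q_ij - q_i q_j), with
    q_i the probability species i is absent from the subsample.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=float)
    N = counts.sum()

    def log_c(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    def absent(m):
        if N - m < n:
            return 0.0
        return float(np.exp(log_c(N - m, n) - log_c(N, n)))

    q = np.array([absent(c) for c in counts])
    var = float((q * (1 - q)).sum())
    for i in range(len(counts)):
        for j in range(i + 1, len(counts)):
            var += 2 * (absent(counts[i] + counts[j]) - q[i] * q[j])
    return max(var, 0.0)


# ---------------------------------------------------------------------------
# exhaustive unrooted-topology enumeration + least-squares branch fitting

def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All unrooted binary topologies over leaves 0..n-1, as edge lists.

    Internal nodes are numbered from n upward. Built by sequential leaf
    insertion on every existing edge: 1, 3, 15, 105, 945, 10395 trees for
    n = 3..8.
    """
    assert n >= 3
    trees = [[(0, n), (1, n), (2, n)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal
                new_edges = edges[:k] + edges[k + 1 :]
                new_edges += [(u, w), (w, v), (leaf, w)]
                new_trees.append(new_edges)
        trees = new_trees
        next_internal += 1
    return trees


def _paths(edges: list[tuple[int, int]], n: int) -> dict[tuple[int, int], list[int]]:
    """Edge indices along the path between every leaf pair (BFS)."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n):
        prev: dict[int, tuple[int, int]] = {a: (-1, -1)}
        queue = [a]
        while queue:
            node = queue.pop(0)
            for nb, eidx in adj[node]:
                if nb not in prev:
                    prev[nb] = (node, eidx)
                    queue.append(nb)
        for b in range(a + 1, n):
            path = []
            node = b
            while node != a:
                parent, eidx = prev[node]
                path.append(eidx)
                node = parent
            out[(a, b)] = path
    return out


def ls_fit(edges: list[tuple[int, int]], D: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares branch lengths for one topology; returns (SSE, lengths)."""
    n = D.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([D[i, j] for i, j in pairs])
    paths = _paths(edges, n)
    for row, (i, j) in enumerate(pairs):
        for eidx in paths[(i, j)]:
            A[row, eidx] = 1.0
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(((A @ lengths - y) ** 2).sum())
    return sse, lengths


def best_ls_topology(D: np.ndarray) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Topology (edge list) minimizing the least-squares fit to D."""
    n = D.shape[0]
    best = None
    for edges in enumerate_topologies(n):
        sse, lengths = ls_fit(edges, D)
        if best is None or sse < best[0]:
            best = (sse, edges, lengths)
    return best[1], best[2]


def topology_splits(edges: list[tuple[int, int]], n: int) -> set[frozenset[int]]:
    """Non-trivial splits (as canonical leaf-index frozensets) of a topology."""
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in edges:
        if u < n or v < n:
            continue  # leaf edge -> trivial split
        # leaves on v's side when edge (u, v) removed
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if nb in seen:
                    continue
                seen.add(nb)
                stack.append(nb)
                if nb < n:
                    side.add(nb)
        if 1 < len(side) < n - 1:
            comp = frozenset(range(n)) - side
            splits.add(frozenset(side) if 0 not in side else frozenset(comp))
    return splits


def random_additive_matrix(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, set[frozenset[int]]]:
    """Random binary tree with positive branch lengths -> its path-distance
    matrix and true split set."""
    edges = enumerate_topologies(n)[int(rng.integers(0, len(enumerate_topologies(n))))]
    lengths = rng.uniform(0.05, 1.0, size=len(edges))
    paths = _paths(edges, n)
    D = np.zeros((n, n))
    for (i, j), path in paths.items():
        D[i, j] = D[j, i] = sum(lengths[e] for e in path)
    return D, topology_splits(edges, n)
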