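"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: partitions are
enumerated exhaustively, nestedness pairs are scored with plain Python loops,
and d' extremes come from enumerating every integer allocation.
"""

from __future__ import annotations

import numpy as np


# -- exhaustive modularity ---------------------------------------------------


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_direct(A: np.ndarray, g: np.ndarray, h: np.ndarray) -> float:
    """Literal double-sum evaluation of weighted bipartite modularity."""
    A = np.asarray(A, dtype=float)
    M = A.sum()
    y = A.sum(axis=1)
    z = A.sum(axis=0)
    total = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            if g[i] == h[j]:
                total += A[i, j] - y[i] * z[j] / M
    return total / M


def exhaustive_best_modularity(A: np.ndarray) -> float:
    """Optimum of Q_W over every joint partition of rows and columns."""
    r, s = A.shape
    nodes = [("r", i) for i in range(r)] + [("c", j) for j in range(s)]
    best = -np.inf
    for part in set_partitions(nodes):
        g = np.zeros(r, dtype=int)
        h = np.zeros(s, dtype=int)
        for m, block in enumerate(part, start=1):
            for cls, idx in block:
                if cls == "r":
                    g[idx] = m
                else:
                    h[idx] = m
        best = max(best, modularity_direct(A, g, h))
    return best


# -- brute-force weighted NODF ------------------------------------------------


def wnodf_brute(A: np.ndarray) -> tuple[float, float, float]:
    """All-pairs weighted NODF via plain loops: (WNODF, WNODFr, WNODFc).

    Rows/columns sorted by decreasing fill (margin breaks ties); a pair
    counts only when the lower member has strictly fewer realized cells.
    """
    A = np.asarray(A, dtype=float)

    def sort_rows(mat):
        keyed = sorted(
            range(mat.shape[0]),
            key=lambda i: (-(mat[i] > 0).sum(), -mat[i].sum()),
        )
        return mat[keyed]

    def pair_scores(mat):
        scores = []
        n = mat.shape[0]
        for u in range(n):
            for v in range(u + 1, n):
                fu = int((mat[u] > 0).sum())
                fv = int((mat[v] > 0).sum())
                if fv >= fu or fv == 0:
                    scores.append(0.0)
                    continue
                overlap = sum(
                    1 for j in range(mat.shape[1]) if 0 < mat[v, j] < mat[u, j]
                )
                scores.append(100.0 * overlap / fv)
        return scores

    mat = sort_rows(A)
    mat = sort_rows(mat.T).T
    rs = pair_scores(mat)
    cs = pair_scores(mat.T)
    both = rs + cs
    return (
        float(np.mean(both)),
        float(np.mean(rs)),
        float(np.mean(cs)),
    )


# -- exhaustive d' allocations -------------------------------------------------


def compositions(total: int, parts: int):
    """All non-negative integer tuples of length ``parts`` summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def d_of_allocation(a, z_others, M) -> float:
    a = np.asarray(a, dtype=float)
    y = a.sum()
    total = 0.0
    for j in range(len(a)):
        if a[j] > 0:
            p = a[j] / y
            q = (z_others[j] + a[j]) / M
            total += p * np.log(p / q)
    return total


def exhaustive_d_extremes(y: int, z_others: np.ndarray, M: float) -> tuple[float, float]:
    """(d_min, d_max) over every integer allocation of y across the columns."""
    ds = [d_of_allocation(a, z_others, M) for a in compositions(y, len(z_others))]
    return min(ds), max(ds)
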