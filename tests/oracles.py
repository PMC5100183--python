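"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: plain-Python dynamic programming,
explicit normal equations, a hand union-find — so that the production code's
vectorized/jitted/graph-library paths are checked against a second,
independent route.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def overlap_dp(a: str, b: str):
    """Free-end-gap overlap DP, match +1 / mismatch 0 / gap -1, pure Python.

    Same recurrence and tie-breaking (diagonal > up > left; end cell by score,
    then matches, then fewest columns, last column scanned before last row) as
    the production aligner.  Returns (matches, columns, overlap_length).
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    M = [[0] * (m + 1) for _ in range(n + 1)]
    C = [[0] * (m + 1) for _ in range(n + 1)]
    U = [[0] * (m + 1) for _ in range(n + 1)]
    V = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else 0
            sd = S[i - 1][j - 1] + match
            su = S[i - 1][j] - 1
            sl = S[i][j - 1] - 1
            if sd >= su and sd >= sl:
                S[i][j] = sd
                M[i][j] = M[i - 1][j - 1] + match
                C[i][j] = C[i - 1][j - 1] + 1
                U[i][j] = U[i - 1][j - 1]
                V[i][j] = V[i - 1][j - 1]
            elif su >= sl:
                S[i][j] = su
                M[i][j] = M[i - 1][j]
                C[i][j] = C[i - 1][j] + 1
                U[i][j] = U[i - 1][j] + 1
                V[i][j] = V[i - 1][j]
            else:
                S[i][j] = sl
                M[i][j] = M[i][j - 1]
                C[i][j] = C[i][j - 1] + 1
                U[i][j] = U[i][j - 1]
                V[i][j] = V[i][j - 1] + 1
    best = None
    for i in range(1, n + 1):
        cell = (S[i][m], M[i][m], -C[i][m], U[i][m], V[i][m])
        if best is None or cell[:3] > best[:3]:
            best = cell
    for j in range(1, m + 1):
        cell = (S[n][j], M[n][j], -C[n][j], U[n][j], V[n][j])
        if cell[:3] > best[:3]:
            best = cell
    _, matches, neg_cols, ups, lefts = best
    columns = -neg_cols
    return matches, columns, columns - max(ups, lefts)


def best_overlap(a: str, b: str, min_overlap_frac=0.55, min_identity=0.90):
    """Reimplementation of the hit decision on top of the Python DP.

    Returns (identity, orientation) of the best accepted overlap, or None.
    Canonicalizes argument order the same way as the production code.
    """
    if (len(b), b) < (len(a), a):
        a, b = b, a
    need = min_overlap_frac * min(len(a), len(b))
    best = None
    for orient in ("same", "reverse"):
        bb = b if orient == "same" else revcomp(b)
        matches, columns, overlap_length = overlap_dp(a, bb)
        if columns == 0 or overlap_length < need:
            continue
        identity = matches / columns
        if identity < min_identity:
            continue
        key = (identity, matches, 1 if orient == "same" else 0)
        if best is None or key > best[0]:
            best = (key, identity, orient)
    if best is None:
        return None
    return best[1], best[2]


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)

    def groups(self) -> list[frozenset[int]]:
        out: dict[int, set[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), set()).add(i)
        return [frozenset(g) for g in out.values()]


def cluster_partition(edges, n: int) -> set[frozenset[int]]:
    """Connected components (size >= 2) from an edge list via union-find."""
    uf = UnionFind(n)
    for i, j in edges:
        uf.union(i, j)
    return {g for g in uf.groups() if len(g) >= 2}


def polyfit_normal_equations(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """OLS polynomial coefficients from explicitly assembled normal equations."""
    powers = [np.sum(x ** p) for p in range(2 * degree + 1)]
    A = np.array([[powers[i + j] for j in range(degree + 1)] for i in range(degree + 1)])
    rhs = np.array([np.sum(y * x ** i) for i in range(degree + 1)])
    return np.linalg.solve(A, rhs)


def g_statistic(table: np.ndarray) -> tuple[float, int]:
    """Hand computation of G = 2 sum O ln(O/E) and its degrees of freedom."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    g = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                e = table[i, :].sum() * table[:, j].sum() / total
                g += 2.0 * o * math.log(o / e)
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return g, dof


def methylation_level(p: float) -> str:
    if p < 0.25:
        return "low"
    if p > 0.75:
        return "high"
    return "intermediate"


def ols_slope(x: np.ndarray, y: np.ndarray):
    """Closed-form simple linear regression: slope, intercept, r^2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 1.0
    return slope, intercept, r2
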