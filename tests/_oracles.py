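"""Independent reference implementations used as test oracles.

Each function here is deliberately written as a direct transcription of the
defining formula (loops, exact integer arithmetic, exhaustive enumeration)
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def hypergeom_upper_tail(N: int, M: int, n: int, x: int) -> float:
    """P(X >= x) by exact integer combinatorics."""
    total = math.comb(N, n)
    count = sum(math.comb(M, k) * math.comb(N - M, n - k)
                for k in range(x, min(M, n) + 1))
    return count / total


def hypergeom_by_enumeration(N: int, M: int, n: int, x: int) -> float:
    """P(X >= x) by literally enumerating all C(N, n) draws (tiny N only)."""
    marked = set(range(M))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(marked.intersection(draw)) >= x)
    return hits / math.comb(N, n)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """q_(i) = min_{j >= i} p_(j) * m / j, written as the literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q


def concordance_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of concordant (pos, neg) pairs, ties half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    wins = sum(1.0 if sp > sn else (0.5 if sp == sn else 0.0)
               for sp in pos for sn in neg)
    return wins / total


def pearson_r(u, v) -> float:
    """Textbook Pearson formula with explicit sums."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(u)
    um, vm = u.mean(), v.mean()
    num = sum((u[i] - um) * (v[i] - vm) for i in range(n))
    den = math.sqrt(sum((x - um) ** 2 for x in u)) * \
        math.sqrt(sum((x - vm) ** 2 for x in v))
    return num / den


def naive_relieff(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """Loop-based ReliefF for binary labels: range-normalized features,
    Manhattan nearest hits/misses, weight = mean miss diff - mean hit diff
    accumulated over all instances and divided by n."""
    X = np.asarray(X, dtype=float)  # samples x features
    y = np.asarray(y)
    n, g = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    w = np.zeros(g)
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            d = 0.0
            for f in range(g):
                if span[f] > 0:
                    d += abs(X[i, f] - X[j, f]) / span[f]
            dists.append((d, j))
        dists.sort(key=lambda t: t[0])
        hits = [j for _, j in dists if y[j] == y[i]][:k]
        misses = [j for _, j in dists if y[j] != y[i]][:k]
        for f in range(g):
            if span[f] == 0:
                continue
            hit_diff = np.mean([abs(X[i, f] - X[j, f]) / span[f] for j in hits])
            miss_diff = np.mean([abs(X[i, f] - X[j, f]) / span[f] for j in misses])
            w[f] += miss_diff - hit_diff
    return w / n


def brute_force_shortest_paths(g: nx.Graph, source: str, target: str):
    """All minimum-hop simple paths by exhaustive enumeration (<= 20 nodes)."""
    if source not in g or target not in g:
        return []
    paths = [p for p in nx.all_simple_paths(g, source, target)]
    if not paths:
        return []
    best = min(len(p) for p in paths)
    return sorted([p for p in paths if len(p) == best])


def dense_pair_product_correlations(X: np.ndarray, genes: list[str],
                                    s: np.ndarray) -> dict:
    """All-at-once per-pair np.corrcoef of products vs score."""
    order = np.argsort(genes)
    genes = [genes[i] for i in order]
    X = X[order]
    out = {}
    G = len(genes)
    for i in range(G):
        for j in range(i + 1, G):
            prod = X[i] * X[j]
            if prod.std() == 0:
                continue
            out[(genes[i], genes[j])] = float(np.corrcoef(prod, s)[0, 1])
    return out
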