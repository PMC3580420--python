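"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and independent of the package
implementation paths it checks: exhaustive enumeration of the
fixed-degree-sequence graph ensemble, naive pair/triple link counting,
exact rational hypergeometric tails, and a literal step-up adjustment.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def enumerate_degree_sequence_graphs(deg: tuple[int, ...]) -> list[frozenset[tuple[int, int]]]:
    """All labeled simple graphs with the given degree sequence.

    Backtracking: the first node with residual degree gets all its edges
    chosen at once, which enumerates each graph exactly once.
    """
    n = len(deg)
    out: list[frozenset[tuple[int, int]]] = []

    def rec(residual: list[int], edges: set[tuple[int, int]]) -> None:
        i = -1
        for k in range(n):
            if residual[k] > 0:
                i = k
                break
        if i < 0:
            out.append(frozenset(edges))
            return
        need = residual[i]
        partners = [
            j
            for j in range(n)
            if j != i and residual[j] > 0 and (min(i, j), max(i, j)) not in edges
        ]
        if len(partners) < need:
            return
        for combo in itertools.combinations(partners, need):
            r2 = list(residual)
            r2[i] = 0
            new = set(edges)
            for j in combo:
                r2[j] -= 1
                new.add((min(i, j), max(i, j)))
            rec(r2, new)

    rec(list(deg), set())
    return out


def brute_direct_count(edges, ags, fgs) -> int:
    """Edges with one endpoint in each set, counted by literal scan."""
    total = 0
    for u, v in edges:
        if (u in ags and v in fgs) or (u in fgs and v in ags):
            total += 1
    return total


def brute_indirect_count(edges, ags, fgs) -> int:
    """Length-2 paths a-x-f between the sets, one count per unordered path."""
    nbr: dict = {}
    for u, v in edges:
        nbr.setdefault(u, set()).add(v)
        nbr.setdefault(v, set()).add(u)
    total = 0
    seen = set()
    for a in ags:
        for f in fgs:
            if a == f:
                continue
            pair = frozenset((a, f))
            if pair in seen:
                continue
            seen.add(pair)
            total += len((nbr.get(a, set()) & nbr.get(f, set())) - {a, f})
    return total


def ensemble_moments(deg, ags, fgs, mode: str):
    """Exact mean/sd/4th central moment of the link count over the uniform
    fixed-degree-sequence ensemble (population moments)."""
    graphs = enumerate_degree_sequence_graphs(tuple(deg))
    counter = brute_direct_count if mode == "direct" else brute_indirect_count
    vals = [counter(g, ags, fgs) for g in graphs]
    n = len(vals)
    mu = sum(vals) / n
    var = sum((v - mu) ** 2 for v in vals) / n
    mu4 = sum((v - mu) ** 4 for v in vals) / n
    return mu, var**0.5, mu4, n


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n) as an exact rational."""
    den = comb(N, n)
    num = 0
    for j in range(max(k, 0, n - (N - K)), min(n, K) + 1):
        num += comb(K, j) * comb(N - K, n - j)
    return Fraction(num, den)


def hand_bh(pvals: list[float]) -> list[float]:
    """Literal Benjamini-Hochberg step-up (independent of the package)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def graph_with_capped_degrees(rng, n_low=5, n_high=9, p=0.4, cap=3, min_edges=3):
    """Random small graph with all degrees <= cap (as an edge list)."""
    import networkx as nx

    while True:
        n = int(rng.integers(n_low, n_high))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        while any(d > cap for _, d in g.degree()):
            u = max(g.degree(), key=lambda x: x[1])[0]
            v = next(iter(g[u]))
            g.remove_edge(u, v)
        if g.number_of_edges() >= min_edges:
            return n, sorted(tuple(sorted(e)) for e in g.edges())
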