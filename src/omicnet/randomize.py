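"""Degree-preserving network randomization and null-moment estimation.

The randomization primitive is the classic double-edge swap: two edges
``(a, b)`` and ``(c, d)`` are replaced by ``(a, d)`` and ``(c, b)`` (with a
random choice of orientation).  A proposal that would create a self-loop or
a duplicate edge is rejected, which preserves every node degree and the
total edge count exactly.

Budget convention
-----------------
``rewire`` runs ``ceil(swap_factor * |E|)`` swap *proposals* (the "lazy"
Markov chain: rejected proposals leave the graph in place but consume
budget).  This chain has the uniform distribution over the fixed-degree-
sequence ensemble of simple graphs as its stationary distribution.  The
alternative convention of counting only successful swaps conditions each
step on success, which makes the stationary distribution proportional to
the number of valid swaps per graph -- an ensemble bias that is measurable
on small graphs.  Counting successes can be requested with
``budget="successes"`` (capped at ``100x`` the budget in attempts), but the
uniform default is used throughout the package.

Null moments for set-pair link counts are estimated from ``n_perm``
independently rewired replicas, each seeded from ``(seed, replica_index)``
and each starting from the original network so that ensemble members are
independent.  :class:`RewiredEnsemble` precomputes the replicas once and
scores any number of set pairs against them, which is how a single batch of
permutations serves a whole result matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import GeneNetwork, GeneSet

__all__ = ["NullMoments", "rewire", "estimate_null", "RewiredEnsemble"]


@dataclass(frozen=True)
class NullMoments:
    """Sample mean and standard deviation of a link count under the null.

    ``sd`` uses the ``n_perm - 1`` denominator.
    """

    mean: float
    sd: float
    n_perm: int

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.mean < 0:
            raise ValueError("mean must be >= 0")


def _swap_edges(
    edges: np.ndarray,
    n_nodes: int,
    n_budget: int,
    rng: np.random.Generator,
    count_successes: bool = False,
) -> tuple[np.ndarray, int]:
    """Run the double-edge-swap chain on an ``(m, 2)`` edge-index array.

    Returns a new array (rows canonicalised ``u < v``) and the number of
    successful swaps performed.
    """
    m = edges.shape[0]
    if m < 2 or n_budget <= 0:
        return edges.copy(), 0
    eu = edges[:, 0].tolist()
    ev = edges[:, 1].tolist()
    N = n_nodes
    present = set()
    for a, b in zip(eu, ev):
        present.add(a * N + b if a < b else b * N + a)

    successes = 0
    attempts = 0
    max_attempts = 100 * n_budget
    done = 0
    # Pre-draw randomness in batches; the loop itself is pure Python but
    # every operation is O(1) on plain ints.
    batch = min(max(n_budget, 1024), 1 << 20)
    while done < n_budget and attempts < max_attempts:
        take = min(batch, max_attempts - attempts)
        idx = rng.integers(0, m, size=2 * take).tolist()
        flips = rng.integers(0, 2, size=take).tolist()
        for t in range(take):
            if done >= n_budget:
                break
            attempts += 1
            if not count_successes:
                done += 1
            i = idx[2 * t]
            j = idx[2 * t + 1]
            if i == j:
                continue
            a = eu[i]
            b = ev[i]
            c = eu[j]
            d = ev[j]
            if flips[t]:
                c, d = d, c
            # proposal: (a,b),(c,d) -> (a,d),(c,b)
            if a == d or c == b:
                continue
            k1 = a * N + d if a < d else d * N + a
            k2 = c * N + b if c < b else b * N + c
            if k1 in present or k2 in present:
                continue
            k_ab = a * N + b if a < b else b * N + a
            k_cd = c * N + d if c < d else d * N + c
            present.discard(k_ab)
            present.discard(k_cd)
            present.add(k1)
            present.add(k2)
            eu[i] = a if a < d else d
            ev[i] = d if a < d else a
            eu[j] = c if c < b else b
            ev[j] = b if c < b else c
            successes += 1
            if count_successes:
                done += 1
    out = np.column_stack([np.asarray(eu, dtype=np.int64), np.asarray(ev, dtype=np.int64)])
    return out, successes


def rewire(
    net: GeneNetwork,
    swap_factor: float = 10.0,
    seed: int = 0,
    budget: str = "attempts",
) -> GeneNetwork:
    """Return a degree-preserving randomization of ``net``.

    Parameters
    ----------
    swap_factor:
        The chain runs ``ceil(swap_factor * |E|)`` steps (see module notes
        for the budget convention).
    seed:
        Seed for the proposal stream; identical seeds give identical output.
    budget:
        ``"attempts"`` (default, uniform stationary distribution) or
        ``"successes"`` (count only successful swaps, capped at 100x the
        budget in proposals).

    The node set, per-node degrees and the edge count of the output equal
    those of the input exactly.  Graphs admitting no valid swap (for
    example a star) are returned unchanged with a warning.  Evidence tags
    are not carried over: rewired edges are synthetic.
    """
    if swap_factor <= 0:
        raise ValueError("swap_factor must be positive")
    if budget not in ("attempts", "successes"):
        raise ValueError(f"unknown budget convention {budget!r}")
    node_list, _, edges = net.to_arrays()
    m = edges.shape[0]
    if m < 2:
        warnings.warn("rewire: fewer than 2 edges, returning the network unchanged")
        return net.copy()
    rng = np.random.default_rng([int(seed)])
    n_budget = math.ceil(swap_factor * m)
    new_edges, successes = _swap_edges(
        edges, len(node_list), n_budget, rng, count_successes=(budget == "successes")
    )
    if successes == 0:
        warnings.warn("rewire: no valid swap was performed; graph returned unchanged")
    out = GeneNetwork()
    for g in node_list:
        out.add_node(g)
    for u, v in new_edges:
        out.add_edge(node_list[int(u)], node_list[int(v)])
    return out


class RewiredEnsemble:
    """A batch of independently rewired replicas of one network.

    Replica ``i`` is produced by an independent chain seeded with
    ``(seed, i)``, always starting from the original network.  The ensemble
    exposes per-replica link counts and null moments for arbitrary gene-set
    pairs, so one batch of permutations can score a whole matrix of tests.
    """

    def __init__(
        self,
        net: GeneNetwork,
        n_perm: int = 50,
        swap_factor: float = 10.0,
        seed: int = 0,
    ) -> None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if swap_factor <= 0:
            raise ValueError("swap_factor must be positive")
        self.n_perm = int(n_perm)
        self.swap_factor = float(swap_factor)
        self.seed = int(seed)
        self.node_list, self.index, self._base_edges = net.to_arrays()
        self.n_nodes = len(self.node_list)
        m = self._base_edges.shape[0]
        n_budget = math.ceil(swap_factor * m) if m >= 2 else 0
        self._perm_edges: list[np.ndarray] = []
        for i in range(self.n_perm):
            rng = np.random.default_rng([self.seed, i])
            replica, _ = _swap_edges(self._base_edges, self.n_nodes, n_budget, rng)
            self._perm_edges.append(replica)
        self._adj_cache: list[sp.csr_matrix | None] = [None] * self.n_perm
        self._base_adj: sp.csr_matrix | None = None

    # -- masks and counting -------------------------------------------

    def mask(self, genes) -> np.ndarray:
        """Boolean node mask for a gene collection (unknown symbols ignored)."""
        if isinstance(genes, GeneSet):
            genes = genes.genes
        out = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            i = self.index.get(g)
            if i is not None:
                out[i] = True
        return out

    def _adjacency(self, edges: np.ndarray) -> sp.csr_matrix:
        n = self.n_nodes
        if edges.shape[0] == 0:
            return sp.csr_matrix((n, n), dtype=np.int64)
        rows = np.concatenate([edges[:, 0], edges[:, 1]])
        cols = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.ones(rows.shape[0], dtype=np.int64)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def _replica_adj(self, i: int) -> sp.csr_matrix:
        if self._adj_cache[i] is None:
            self._adj_cache[i] = self._adjacency(self._perm_edges[i])
        return self._adj_cache[i]

    def base_adjacency(self) -> sp.csr_matrix:
        if self._base_adj is None:
            self._base_adj = self._adjacency(self._base_edges)
        return self._base_adj

    @staticmethod
    def direct_count(edges: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> int:
        """Distinct edges with one endpoint in each set (shared genes count once)."""
        if edges.shape[0] == 0:
            return 0
        u = edges[:, 0]
        v = edges[:, 1]
        hit = (mask_a[u] & mask_b[v]) | (mask_b[u] & mask_a[v])
        return int(np.count_nonzero(hit))

    @staticmethod
    def indirect_count(adj: sp.csr_matrix, mask_a: np.ndarray, mask_b: np.ndarray) -> int:
        """Distinct length-2 paths a-x-f with a in A, f in B, x not an endpoint.

        Each unordered path is counted once even when both endpoints belong
        to both sets.  The intermediate gene may be a member of either set.
        """
        ia = np.flatnonzero(mask_a)
        ib = np.flatnonzero(mask_b)
        if ia.size == 0 or ib.size == 0:
            return 0
        paths = adj[ia] @ adj[:, ib]  # paths[a, f] = |N(a) & N(f)|; diagonal of adj is 0
        total = int(paths.sum())
        both = np.flatnonzero(mask_a & mask_b)
        if both.size:
            inner = adj[both] @ adj[:, both]
            diag = int(inner.diagonal().sum())  # a == f terms (degree of each shared gene)
            dup = (int(inner.sum()) - diag) // 2  # unordered pairs inside A&B counted twice
            total -= diag + dup
        return total

    def _count(self, edges: np.ndarray, adj_getter, mask_a, mask_b, mode: str) -> int:
        if mode == "direct":
            return self.direct_count(edges, mask_a, mask_b)
        if mode == "indirect":
            return self.indirect_count(adj_getter(), mask_a, mask_b)
        raise ValueError(f"unknown mode {mode!r}")

    def observed_count(self, ags, fgs, mode: str = "direct") -> int:
        """Link count on the original (unpermuted) network."""
        ma, mb = self.mask(ags), self.mask(fgs)
        return self._count(self._base_edges, self.base_adjacency, ma, mb, mode)

    def null_counts(self, ags, fgs, mode: str = "direct") -> np.ndarray:
        """Per-replica link counts, shape ``(n_perm,)``."""
        ma, mb = self.mask(ags), self.mask(fgs)
        out = np.empty(self.n_perm, dtype=np.int64)
        for i in range(self.n_perm):
            out[i] = self._count(
                self._perm_edges[i], lambda i=i: self._replica_adj(i), ma, mb, mode
            )
        return out

    def null_moments(self, ags, fgs, mode: str = "direct") -> NullMoments:
        """Sample mean/sd of the null link count (n-1 denominator)."""
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2 for a standard deviation")
        counts = self.null_counts(ags, fgs, mode)
        return NullMoments(
            mean=float(counts.mean()),
            sd=float(counts.std(ddof=1)),
            n_perm=self.n_perm,
        )


def estimate_null(
    net: GeneNetwork,
    ags: GeneSet,
    fgs: GeneSet,
    mode: str = "direct",
    n_perm: int = 50,
    swap_factor: float = 10.0,
    seed: int = 0,
) -> NullMoments:
    """Estimate null link-count moments from ``n_perm`` rewired replicas.

    Raises ``ValueError`` when ``n_perm < 2`` (the standard deviation is
    undefined).  Genes absent from the network contribute nothing.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2 (sd undefined otherwise)")
    ens = RewiredEnsemble(net, n_perm=n_perm, swap_factor=swap_factor, seed=seed)
    return ens.null_moments(ags, fgs, mode)
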