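"""Network enrichment analysis (NEA).

For an altered gene set (AGS) *i* and a functional gene set (FGS) *j*, the
enrichment of network connections between them is scored as

    z = (n_obs - null_mean) / null_sd

where the null mean and standard deviation of the link count are learned
from degree-preserving network permutations.  Two link statistics are
supported: ``direct`` counts edges with one endpoint in each set, and
``indirect`` counts length-2 paths through a shared network neighbor.
Under the null the z-scores are approximately standard normal, so a
one-sided (upper-tail, enrichment) P-value is attached; depletion shows up
as negative z only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneNetwork, GeneSet
from .randomize import NullMoments, RewiredEnsemble

__all__ = [
    "NeaResult",
    "count_direct_links",
    "count_indirect_links",
    "z_to_p",
    "nea_test",
    "nea_single_gene",
    "nea_matrix",
    "estimate_fdr",
    "pathway_connectivity_filter",
    "results_to_frame",
]


@dataclass
class NeaResult:
    """One AGS-FGS (or gene-FGS) enrichment test.

    ``z`` is ``nan`` when the null sd is zero and the observed count equals
    the null mean (the statistic is undefined; ``p`` is then 1).
    """

    ags: GeneSet
    fgs: GeneSet
    mode: str
    n_obs: int
    null: NullMoments
    z: float
    p: float
    fdr: float | None = None
    significant: bool | None = None

    @property
    def ags_name(self) -> str:
        return self.ags.name

    @property
    def fgs_name(self) -> str:
        return self.fgs.name

    def as_dict(self) -> dict:
        return {
            "ags": self.ags_name,
            "fgs": self.fgs_name,
            "mode": self.mode,
            "n_obs": self.n_obs,
            "mean": self.null.mean,
            "sd": self.null.sd,
            "z": self.z,
            "p": self.p,
            "fdr": self.fdr,
            "significant": self.significant,
        }


def _masks_for(net: GeneNetwork, s: GeneSet) -> set[str]:
    return s.genes & net.nodes


def count_direct_links(net: GeneNetwork, ags: GeneSet, fgs: GeneSet) -> int:
    """Number of distinct edges {u, v} with one endpoint in each set.

    An edge whose two endpoints both lie in the intersection of the sets is
    counted once.
    """
    a = _masks_for(net, ags)
    f = _masks_for(net, fgs)
    count = 0
    for u, v in net.edges():
        if (u in a and v in f) or (u in f and v in a):
            count += 1
    return count


def count_indirect_links(net: GeneNetwork, ags: GeneSet, fgs: GeneSet) -> int:
    """Number of distinct length-2 paths a-x-f between the sets.

    ``a`` ranges over the AGS, ``f`` over the FGS, ``a != f``; the
    intermediate ``x`` may belong to either set but is not an endpoint of
    its own path.  Each unordered (a, x, f) path is counted once; a direct
    a-f edge neither adds to nor removes from the count.
    """
    a_set = _masks_for(net, ags)
    f_set = _masks_for(net, fgs)
    count = 0
    seen: set[frozenset] = set()
    for g in a_set:
        ng = net.neighbors(g)
        for h in f_set:
            if h == g:
                continue
            pair = frozenset((g, h))
            if pair in seen:
                continue
            seen.add(pair)
            shared = (ng & net.neighbors(h)) - {g, h}
            count += len(shared)
    return count


def z_to_p(z: float) -> float:
    """One-sided upper-tail standard normal probability for a z-score."""
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    return float(stats.norm.sf(z))


def _score(n_obs: int, null: NullMoments) -> tuple[float, float]:
    """(z, p) with the degenerate sd == 0 cases resolved."""
    if null.sd > 0:
        z = (n_obs - null.mean) / null.sd
        return z, z_to_p(z)
    if n_obs == null.mean:
        return float("nan"), 1.0
    # sd == 0 but the observation differs from the (constant) null
    return (math.inf if n_obs > null.mean else -math.inf), (0.0 if n_obs > null.mean else 1.0)


def nea_test(
    net: GeneNetwork,
    ags: GeneSet,
    fgs: GeneSet,
    mode: str = "direct",
    n_perm: int = 50,
    swap_factor: float = 10.0,
    seed: int = 0,
    ensemble: RewiredEnsemble | None = None,
) -> NeaResult:
    """Test one AGS against one FGS.

    A precomputed :class:`RewiredEnsemble` may be passed so that one batch
    of permutations serves many tests; otherwise one is built from
    ``(n_perm, swap_factor, seed)``.
    """
    if ensemble is None:
        if n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        ensemble = RewiredEnsemble(net, n_perm=n_perm, swap_factor=swap_factor, seed=seed)
    n_obs = ensemble.observed_count(ags, fgs, mode)
    null = ensemble.null_moments(ags, fgs, mode)
    z, p = _score(n_obs, null)
    return NeaResult(ags=ags, fgs=fgs, mode=mode, n_obs=n_obs, null=null, z=z, p=p)


def nea_single_gene(
    net: GeneNetwork,
    gene: str,
    reference: GeneSet,
    mode: str = "direct",
    n_perm: int = 50,
    swap_factor: float = 10.0,
    seed: int = 0,
    ensemble: RewiredEnsemble | None = None,
) -> NeaResult:
    """Test a single gene against a reference set (the gene itself removed)."""
    if gene not in net.nodes:
        raise ValueError(f"gene {gene!r} is not in the network")
    rest = reference.genes - {gene}
    if not rest:
        raise ValueError(f"reference set {reference.name!r} is empty after removing {gene!r}")
    ags = GeneSet(name=gene, genes=frozenset({gene}), cls="custom")
    fgs = GeneSet(name=reference.name, genes=rest, cls=reference.cls)
    return nea_test(
        net, ags, fgs, mode=mode, n_perm=n_perm, swap_factor=swap_factor, seed=seed, ensemble=ensemble
    )


def nea_matrix(
    net: GeneNetwork,
    ags_list: Sequence[GeneSet],
    fgs_list: Sequence[GeneSet],
    mode: str = "direct",
    n_perm: int = 50,
    swap_factor: float = 10.0,
    seed: int = 0,
    include_ags_vs_ags: bool = False,
    fdr_method: str = "left_tail",
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.10,
    n_random: int = 20,
) -> list[NeaResult]:
    """All AGS x FGS tests (plus AGS-AGS pairs on request) with FDR filled.

    One permutation batch is shared across all pairs.  Each result is
    flagged ``significant`` when ``p < p_threshold`` and
    ``fdr < fdr_threshold``.
    """
    if not ags_list or not fgs_list:
        raise ValueError("ags_list and fgs_list must be non-empty")
    ensemble = RewiredEnsemble(net, n_perm=n_perm, swap_factor=swap_factor, seed=seed)
    results: list[NeaResult] = []
    for ags in ags_list:
        for fgs in fgs_list:
            results.append(nea_test(net, ags, fgs, mode=mode, ensemble=ensemble))
    if include_ags_vs_ags:
        for i in range(len(ags_list)):
            for j in range(i + 1, len(ags_list)):
                results.append(nea_test(net, ags_list[i], ags_list[j], mode=mode, ensemble=ensemble))
    estimate_fdr(results, method=fdr_method, net=net, seed=seed + 1, n_random=n_random, ensemble=ensemble)
    for r in results:
        r.significant = bool(r.p < p_threshold and r.fdr is not None and r.fdr < fdr_threshold)
    return results


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def _degree_bins(net_degrees: dict[str, int]) -> dict[str, list[str]]:
    """Genes grouped by floor(log2(degree)) bins; degree 0 forms its own bin."""
    bins: dict[int, list[str]] = {}
    for g, d in net_degrees.items():
        b = -1 if d == 0 else int(math.floor(math.log2(d)))
        bins.setdefault(b, []).append(g)
    return {b: sorted(genes) for b, genes in bins.items()}


def _sample_matched_set(
    genes: frozenset[str],
    degree_of: dict[str, int],
    bins: dict[int, list[str]],
    rng: np.random.Generator,
) -> frozenset[str]:
    """Random set matching the size and binned degree profile of ``genes``."""
    need: dict[int, int] = {}
    for g in genes:
        d = degree_of.get(g, 0)
        b = -1 if d == 0 else int(math.floor(math.log2(d)))
        need[b] = need.get(b, 0) + 1
    out: list[str] = []
    for b, k in sorted(need.items()):
        pool = bins[b]
        picked = rng.choice(len(pool), size=k, replace=False)
        out.extend(pool[i] for i in picked)
    return frozenset(out)


def estimate_fdr(
    results: list[NeaResult],
    method: str = "left_tail",
    net: GeneNetwork | None = None,
    n_random: int = 20,
    seed: int = 0,
    n_perm: int = 50,
    swap_factor: float = 10.0,
    ensemble: RewiredEnsemble | None = None,
) -> list[NeaResult]:
    """Fill the ``fdr`` field of each result in place (and return the list).

    ``left_tail``
        FDR(z0) = count(z <= -z0) / count(z >= z0) over the result list:
        the depletion tail, where no true findings are expected, estimates
        the false-positive load of the enrichment tail.  Clipped to [0, 1].

    ``random_sets``
        For each observed z0, the mean number of random-AGS z-scores
        reaching z0 per randomization, divided by the observed number
        reaching z0.  Random sets match the original AGS in size and in
        binned degree profile (bins at powers of two of the node degree).
        Requires ``net``.

    Results with undefined z receive FDR 1.
    """
    if not results:
        raise ValueError("estimate_fdr needs at least one result")
    zs = np.array([r.z for r in results], dtype=float)
    finite = np.isfinite(zs)

    def obs_ge(z0: float) -> int:
        return int(np.count_nonzero(zs[finite] >= z0) + np.count_nonzero(np.isposinf(zs)))

    if method == "left_tail":
        for r in results:
            if not math.isfinite(r.z):
                r.fdr = 1.0 if math.isnan(r.z) or r.z < 0 else 0.0
                continue
            den = obs_ge(r.z)
            num = int(np.count_nonzero(zs[finite] <= -r.z) + np.count_nonzero(np.isneginf(zs)))
            r.fdr = 0.0 if den == 0 else float(min(1.0, num / den))
        return results

    if method == "random_sets":
        if net is None:
            raise ValueError("random_sets FDR requires the network")
        if n_random < 1:
            raise ValueError("n_random must be >= 1")
        if ensemble is None:
            ensemble = RewiredEnsemble(net, n_perm=n_perm, swap_factor=swap_factor, seed=seed)
        degree_of = {g: net.degree(g) for g in net.nodes}
        bins = _degree_bins(degree_of)
        rand_z = np.empty((n_random, len(results)), dtype=float)
        for rep in range(n_random):
            rng = np.random.default_rng([seed, 7919, rep])
            for k, r in enumerate(results):
                in_net = r.ags.genes & net.nodes
                if not in_net:
                    rand_z[rep, k] = np.nan
                    continue
                rand_genes = _sample_matched_set(frozenset(in_net), degree_of, bins, rng)
                rand_ags = GeneSet(name=f"random:{r.ags_name}", genes=rand_genes, cls="custom")
                n_obs = ensemble.observed_count(rand_ags, r.fgs, r.mode)
                null = ensemble.null_moments(rand_ags, r.fgs, r.mode)
                z, _ = _score(n_obs, null)
                rand_z[rep, k] = z
        for r in results:
            if not math.isfinite(r.z):
                r.fdr = 1.0 if math.isnan(r.z) or r.z < 0 else 0.0
                continue
            den = obs_ge(r.z)
            with np.errstate(invalid="ignore"):
                per_rep = np.nansum(rand_z >= r.z, axis=1)
            num = float(per_rep.mean())
            r.fdr = 0.0 if den == 0 else float(min(1.0, num / den))
        return results

    raise ValueError(f"unknown FDR method {method!r}")


def pathway_connectivity_filter(
    results: Sequence[NeaResult],
    min_links: int = 5,
    min_z: float = 2.0,
) -> list[NeaResult]:
    """Keep results with at least ``min_links`` observed links and z above ``min_z``."""
    # nan z compares False; +inf z passes any finite threshold
    return [r for r in results if r.n_obs >= min_links and r.z > min_z]


def results_to_frame(results: Sequence[NeaResult]) -> pd.DataFrame:
    """Tabulate results (ags, fgs, mode, n_obs, mean, sd, z, p, fdr, significant)."""
    return pd.DataFrame([r.as_dict() for r in results])
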