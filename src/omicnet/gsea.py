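"""Overlap-based gene set enrichment (the comparator to NEA).

The classic hypergeometric (odds-ratio) test: for an AGS of size ``n`` and
an FGS of size ``K`` inside a universe of ``N`` genes, the P-value is the
upper tail ``P(X >= k)`` of the hypergeometric distribution at the observed
overlap ``k``.  P-values across a batch are adjusted with the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .network import GeneSet
from .nea import NeaResult

__all__ = ["OverlapResult", "AgreementTable", "hypergeom_test", "bh_adjust", "compare_nea_gsea"]


@dataclass
class OverlapResult:
    """Hypergeometric overlap test for one AGS-FGS pair."""

    ags_name: str
    fgs_name: str
    k: int  # overlap
    n: int  # AGS size
    K: int  # FGS size
    N: int  # universe size
    p: float
    q: float | None = None  # BH-adjusted

    def __post_init__(self) -> None:
        if min(self.k, self.n, self.K, self.N) < 0:
            raise ValueError("counts must be non-negative")
        if self.k > min(self.n, self.K):
            raise ValueError("overlap cannot exceed either set size")

    def as_dict(self) -> dict:
        return {
            "ags": self.ags_name,
            "fgs": self.fgs_name,
            "k": self.k,
            "n": self.n,
            "K": self.K,
            "N": self.N,
            "p": self.p,
            "q": self.q,
        }


def hypergeom_test(ags: GeneSet, fgs: GeneSet, universe: Iterable[str]) -> OverlapResult:
    """Upper-tail hypergeometric test of the overlap between two gene sets.

    Both sets must be contained in the universe.
    """
    uni = frozenset(universe)
    if not ags.genes <= uni:
        missing = sorted(ags.genes - uni)[:10]
        raise ValueError(f"AGS {ags.name!r} not contained in universe (e.g. {missing})")
    if not fgs.genes <= uni:
        missing = sorted(fgs.genes - uni)[:10]
        raise ValueError(f"FGS {fgs.name!r} not contained in universe (e.g. {missing})")
    N = len(uni)
    n = len(ags.genes)
    K = len(fgs.genes)
    k = len(ags.genes & fgs.genes)
    # P(X >= k) for X ~ Hypergeom(N, K, n)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(ags_name=ags.name, fgs_name=fgs.name, k=k, n=n, K=K, N=N, p=min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out.tolist()


def adjust_overlap_results(results: Sequence[OverlapResult]) -> list[OverlapResult]:
    """Fill the ``q`` field of each overlap result (BH over the batch)."""
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return list(results)


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement between NEA and GSEA significance calls."""

    nea_pos_gsea_pos: int
    nea_pos_gsea_neg: int
    nea_neg_gsea_pos: int
    nea_neg_gsea_neg: int

    @property
    def total(self) -> int:
        return (
            self.nea_pos_gsea_pos
            + self.nea_pos_gsea_neg
            + self.nea_neg_gsea_pos
            + self.nea_neg_gsea_neg
        )

    def as_dict(self) -> dict:
        return {
            "nea+/gsea+": self.nea_pos_gsea_pos,
            "nea+/gsea-": self.nea_pos_gsea_neg,
            "nea-/gsea+": self.nea_neg_gsea_pos,
            "nea-/gsea-": self.nea_neg_gsea_neg,
        }


def compare_nea_gsea(
    nea_results: Sequence[NeaResult],
    overlap_results: Sequence[OverlapResult],
    nea_threshold: float = 0.05,
    gsea_threshold: float = 0.05,
    nea_fdr_threshold: float | None = 0.10,
) -> AgreementTable:
    """Cross-tabulate significance calls over matched (AGS, FGS) pairs.

    NEA calls a pair positive when ``p < nea_threshold`` (and, if
    ``nea_fdr_threshold`` is set and the FDR field is filled,
    ``fdr < nea_fdr_threshold``).  GSEA calls a pair positive when the
    BH-adjusted ``q < gsea_threshold``.  The two inputs must cover exactly
    the same pairs; unmatched pairs raise an error listing them.
    """
    nea_by_pair = {(r.ags_name, r.fgs_name): r for r in nea_results}
    gsea_by_pair = {(r.ags_name, r.fgs_name): r for r in overlap_results}
    only_nea = sorted(set(nea_by_pair) - set(gsea_by_pair))
    only_gsea = sorted(set(gsea_by_pair) - set(nea_by_pair))
    if only_nea or only_gsea:
        raise ValueError(
            f"unmatched pairs: NEA-only {only_nea[:10]}, GSEA-only {only_gsea[:10]}"
        )
    cells = {(True, True): 0, (True, False): 0, (False, True): 0, (False, False): 0}
    for pair, nr in nea_by_pair.items():
        gr = gsea_by_pair[pair]
        nea_pos = bool(nr.p < nea_threshold)
        if nea_fdr_threshold is not None and nr.fdr is not None:
            nea_pos = nea_pos and nr.fdr < nea_fdr_threshold
        if gr.q is None:
            raise ValueError(f"overlap result for {pair} has no adjusted q; run adjust_overlap_results")
        gsea_pos = bool(gr.q < gsea_threshold)
        cells[(nea_pos, gsea_pos)] += 1
    return AgreementTable(
        nea_pos_gsea_pos=cells[(True, True)],
        nea_pos_gsea_neg=cells[(True, False)],
        nea_neg_gsea_pos=cells[(False, True)],
        nea_neg_gsea_neg=cells[(False, False)],
    )
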