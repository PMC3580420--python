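"""Genomic filtering stages for multi-omics driver prioritization.

This module implements the filters that turn raw per-gene omics tables and
SNV calls into altered gene sets (AGS):

* copy-number vs expression/protein association (Kruskal-Wallis),
* within-line mRNA-protein correlation (Spearman),
* per-gene cross-line copy-number/response correlation with a
  permutation-based log-ratio control,
* the copy-number-alteration (CNA) correlation filter,
* a network-context filter that keeps CNA genes functionally coupled to
  the SNV-impaired reference set,
* allelic-imbalance calling (heterozygous DNA, monoallelic RNA),
* SNV set construction from externally annotated variants,
* assembly of the per-class AGS list.

The "heterogeneity" SNV filter is approximated by an allele-fraction
floor; the exact upstream rule is unpublished, so the floor is exposed as
a parameter and flagged in the docs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneNetwork, GeneSet
from .nea import nea_single_gene
from .randomize import RewiredEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsTable",
    "VariantRecord",
    "FilterReport",
    "KruskalResult",
    "LogRatioCurve",
    "load_omics_table",
    "load_variants_tsv",
    "write_variants_tsv",
    "load_variants_vcf",
    "write_variants_vcf",
    "cn_expression_association",
    "mrna_protein_correlation",
    "per_gene_cross_line_correlation",
    "permutation_log_ratio",
    "filter_cna_genes",
    "nea_context_filter",
    "call_allelic_imbalance",
    "filter_snvs",
    "build_ags",
]


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass
class OmicsTable:
    """Per-gene, per-cell-line copy number, RPKM and protein intensity.

    Long-format table with columns ``gene``, ``line``, ``copy_number``,
    ``rpkm``, ``protein`` (protein may be missing / NaN).
    """

    data: pd.DataFrame

    REQUIRED = ("gene", "line", "copy_number", "rpkm", "protein")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"omics table missing columns: {missing}")
        if (self.data["copy_number"] < 0).any():
            raise ValueError("copy_number must be >= 0")
        if (self.data["rpkm"] < 0).any():
            raise ValueError("rpkm must be >= 0")

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def for_line(self, line: str) -> pd.DataFrame:
        sub = self.data[self.data["line"] == line]
        if sub.empty:
            raise ValueError(f"no rows for line {line!r}")
        return sub

    def for_gene(self, gene: str) -> pd.DataFrame:
        sub = self.data[self.data["gene"] == gene]
        if sub.empty:
            raise ValueError(f"no rows for gene {gene!r}")
        return sub

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_omics_table(path) -> OmicsTable:
    """Read an omics TSV (columns gene, line, copy_number, rpkm, protein)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "line": str})
    return OmicsTable(df)


@dataclass
class VariantRecord:
    """One SNV with DNA and RNA allele depths and external annotations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    dna_depth: int
    dna_alt_depth: int
    rna_depth: int
    rna_alt_depth: int
    damaging: bool = False
    common_polymorphism: bool = False

    def __post_init__(self) -> None:
        if min(self.dna_depth, self.dna_alt_depth, self.rna_depth, self.rna_alt_depth) < 0:
            raise ValueError("depths must be >= 0")
        if self.dna_alt_depth > self.dna_depth or self.rna_alt_depth > self.rna_depth:
            raise ValueError("alt depth cannot exceed total depth")

    @property
    def dna_af(self) -> float | None:
        return None if self.dna_depth == 0 else self.dna_alt_depth / self.dna_depth

    @property
    def rna_af(self) -> float | None:
        return None if self.rna_depth == 0 else self.rna_alt_depth / self.rna_depth


@dataclass
class FilterReport:
    """Audit trail for one filtering stage."""

    stage: str
    n_in: int
    n_out: int
    params: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError(f"{self.stage}: output ({self.n_out}) exceeds input ({self.n_in})")

    def as_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "params": self.params,
            "details": self.details,
        }


# ---------------------------------------------------------------------------
# Variant IO
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "dna_depth",
    "dna_alt_depth",
    "rna_depth",
    "rna_alt_depth",
    "damaging",
    "common_polymorphism",
]


def load_variants_tsv(
    path,
    damaging_genes: Iterable[str] | None = None,
    polymorphism_sites: Iterable[tuple[str, int]] | None = None,
) -> list[VariantRecord]:
    """Read variants from a flat TSV.

    ``damaging`` / ``common_polymorphism`` columns are optional; external
    annotation lists (damaging gene symbols, known-polymorphism
    (chrom, pos) sites) override/augment them when given.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "gene": str})
    dmg = set(damaging_genes) if damaging_genes is not None else None
    poly = set(polymorphism_sites) if polymorphism_sites is not None else None
    out: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        damaging = bool(getattr(row, "damaging", False))
        common = bool(getattr(row, "common_polymorphism", False))
        if dmg is not None:
            damaging = damaging or row.gene in dmg
        if poly is not None:
            common = common or (row.chrom, int(row.pos)) in poly
        out.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                gene=str(row.gene),
                dna_depth=int(row.dna_depth),
                dna_alt_depth=int(row.dna_alt_depth),
                rna_depth=int(row.rna_depth),
                rna_alt_depth=int(row.rna_alt_depth),
                damaging=damaging,
                common_polymorphism=common,
            )
        )
    return out


def write_variants_tsv(variants: Sequence[VariantRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "dna_depth": v.dna_depth,
                "dna_alt_depth": v.dna_alt_depth,
                "rna_depth": v.rna_depth,
                "rna_alt_depth": v.rna_alt_depth,
                "damaging": int(v.damaging),
                "common_polymorphism": int(v.common_polymorphism),
            }
            for v in variants
        ],
        columns=_VARIANT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: Sequence[VariantRecord], path) -> None:
    """Write variants as an uncompressed VCF with DNA and RNA samples.

    Allele depths go into the AD format field (ref, alt); the gene symbol
    and annotation flags into INFO.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=DMG,Number=0,Type=Flag,Description="Predicted damaging">\n')
        fh.write('##INFO=<ID=CPM,Number=0,Type=Flag,Description="Common polymorphism">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tDNA\tRNA\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos)):
            info = f"GENE={v.gene}"
            if v.damaging:
                info += ";DMG"
            if v.common_polymorphism:
                info += ";CPM"
            dna_ad = f"{v.dna_depth - v.dna_alt_depth},{v.dna_alt_depth}"
            rna_ad = f"{v.rna_depth - v.rna_alt_depth},{v.rna_alt_depth}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tAD\t{dna_ad}\t{rna_ad}\n"
            )


def load_variants_vcf(path) -> list[VariantRecord]:
    """Read variants from a VCF with DNA and RNA samples carrying AD fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if "DNA" not in samples or "RNA" not in samples:
        raise ValueError(f"VCF must contain samples 'DNA' and 'RNA', found {samples}")
    i_dna = samples.index("DNA")
    i_rna = samples.index("RNA")
    out: list[VariantRecord] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"variant {rec.CHROM}:{rec.POS} lacks the AD format field")
        dna_ref, dna_alt = int(ad[i_dna][0]), int(ad[i_dna][1])
        rna_ref, rna_alt = int(ad[i_rna][0]), int(ad[i_rna][1])
        out.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                gene=rec.INFO.get("GENE", "."),
                dna_depth=dna_ref + dna_alt,
                dna_alt_depth=dna_alt,
                rna_depth=rna_ref + rna_alt,
                rna_alt_depth=rna_alt,
                damaging=rec.INFO.get("DMG") is not None,
                common_polymorphism=rec.INFO.get("CPM") is not None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Association and correlation statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


def cn_expression_association(omics: OmicsTable, line: str, response: str = "rpkm") -> KruskalResult:
    """Kruskal-Wallis test of a response across copy-number classes in one line."""
    if response not in ("rpkm", "protein"):
        raise ValueError("response must be 'rpkm' or 'protein'")
    sub = omics.for_line(line)[["copy_number", response]].dropna()
    groups = [g[response].to_numpy() for _, g in sub.groupby("copy_number")]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 copy-number classes in line {line!r}, got {len(groups)}")
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return KruskalResult(h=0.0, df=len(groups) - 1, p=1.0)
    h, p = stats.kruskal(*groups)
    return KruskalResult(h=float(h), df=len(groups) - 1, p=float(p))


def mrna_protein_correlation(omics: OmicsTable, line: str) -> float:
    """Spearman correlation of RPKM vs protein across genes within a line.

    Genes with missing protein values are dropped pairwise.
    """
    sub = omics.for_line(line)[["rpkm", "protein"]].dropna()
    if len(sub) < 3:
        raise ValueError(f"line {line!r} has fewer than 3 complete rpkm/protein pairs")
    rho, _ = stats.spearmanr(sub["rpkm"], sub["protein"])
    return float(rho)


def per_gene_cross_line_correlation(omics: OmicsTable, gene: str, response: str = "rpkm") -> float:
    """Spearman correlation of copy number vs response across cell lines.

    Returns NaN (undefined) when either vector has zero variance; raises
    when fewer than 3 lines carry both values.
    """
    if response not in ("rpkm", "protein"):
        raise ValueError("response must be 'rpkm' or 'protein'")
    sub = omics.for_gene(gene)[["copy_number", response]].dropna()
    if len(sub) < 3:
        raise ValueError(f"gene {gene!r} observed in fewer than 3 lines for {response}")
    cn = sub["copy_number"].to_numpy(dtype=float)
    resp = sub[response].to_numpy(dtype=float)
    if np.all(cn == cn[0]) or np.all(resp == resp[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(cn, resp)
    return float(rho)


def _rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho per row of two equally shaped (G, L) matrices.

    Rows with zero variance in either matrix yield NaN (midranks for ties).
    """
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


@dataclass(frozen=True)
class LogRatioCurve:
    """Observed-vs-permuted correlation counts per threshold (natural log ratio)."""

    thresholds: tuple[float, ...]
    log_ratio: tuple[float, ...]
    observed_counts: tuple[int, ...]
    permuted_mean_counts: tuple[float, ...]


def permutation_log_ratio(
    omics: OmicsTable,
    n_perm: int = 100,
    seed: int = 0,
    response: str = "rpkm",
    thresholds: Sequence[float] | None = None,
) -> LogRatioCurve:
    """Permutation control for the cross-line correlation filter.

    For each threshold t on a grid the curve reports
    ``ln((observed_count(rho >= t) + 0.5) / (mean_permuted_count + 0.5))``
    where the permutation shuffles the line-to-response assignment per
    gene.  The pseudo-count of 0.5 guards against empty permuted tails.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if thresholds is None:
        thresholds = [round(0.1 * i, 1) for i in range(11)]
    wide_cn = omics.data.pivot_table(index="gene", columns="line", values="copy_number")
    wide_r = omics.data.pivot_table(index="gene", columns="line", values=response)
    keep = wide_cn.notna().all(axis=1) & wide_r.notna().all(axis=1)
    cn = wide_cn[keep].to_numpy(dtype=float)
    resp = wide_r[keep].to_numpy(dtype=float)
    if cn.shape[0] < 50:
        raise ValueError(f"need >= 50 genes with complete data, got {cn.shape[0]}")
    obs_rho = _rowwise_spearman(cn, resp)
    obs_counts = [int(np.nansum(obs_rho >= t)) for t in thresholds]
    rng = np.random.default_rng(seed)
    perm_counts = np.zeros((n_perm, len(thresholds)), dtype=float)
    for i in range(n_perm):
        perm_resp = rng.permuted(resp, axis=1)
        rho = _rowwise_spearman(cn, perm_resp)
        for j, t in enumerate(thresholds):
            perm_counts[i, j] = np.nansum(rho >= t)
    mean_perm = perm_counts.mean(axis=0)
    log_ratio = [float(np.log((o + 0.5) / (m + 0.5))) for o, m in zip(obs_counts, mean_perm)]
    return LogRatioCurve(
        thresholds=tuple(float(t) for t in thresholds),
        log_ratio=tuple(log_ratio),
        observed_counts=tuple(obs_counts),
        permuted_mean_counts=tuple(float(m) for m in mean_perm),
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_cna_genes(
    omics: OmicsTable,
    cna_gene_list: Sequence[str],
    corr_threshold: float = 0.8,
    rpkm_min: float = 1.0,
    use_protein: bool = True,
) -> tuple[GeneSet, FilterReport]:
    """Keep CNA genes whose copy number tracks expression (and protein).

    A gene survives when the mean of its cross-line Spearman correlations
    (copy number vs RPKM and, when available and ``use_protein``, copy
    number vs protein) exceeds ``corr_threshold``, and its maximum RPKM
    across lines reaches ``rpkm_min``.  Genes with an undefined RPKM
    correlation (tied copy numbers or responses) are dropped.
    """
    known = set(omics.genes)
    unknown = [g for g in cna_gene_list if g not in known]
    if unknown:
        raise ValueError(f"CNA genes absent from omics table: {sorted(unknown)[:10]}")
    kept: list[str] = []
    per_gene: dict[str, dict] = {}
    for gene in cna_gene_list:
        sub = omics.for_gene(gene)
        rho_r = per_gene_cross_line_correlation(omics, gene, "rpkm")
        rhos = []
        rho_p = float("nan")
        if np.isfinite(rho_r):
            rhos.append(rho_r)
        if use_protein and sub["protein"].notna().sum() >= 3:
            rho_p = per_gene_cross_line_correlation(omics, gene, "protein")
            if np.isfinite(rho_p):
                rhos.append(rho_p)
        max_rpkm = float(sub["rpkm"].max())
        mean_rho = float(np.mean(rhos)) if rhos and np.isfinite(rho_r) else float("nan")
        keep = bool(np.isfinite(mean_rho) and mean_rho > corr_threshold and max_rpkm >= rpkm_min)
        per_gene[gene] = {
            "rho_rpkm": None if not np.isfinite(rho_r) else rho_r,
            "rho_protein": None if not np.isfinite(rho_p) else rho_p,
            "mean_rho": None if not np.isfinite(mean_rho) else mean_rho,
            "max_rpkm": max_rpkm,
            "kept": keep,
        }
        if keep:
            kept.append(gene)
    report = FilterReport(
        stage="filter_cna_genes",
        n_in=len(cna_gene_list),
        n_out=len(kept),
        params={
            "corr_threshold": corr_threshold,
            "rpkm_min": rpkm_min,
            "use_protein": use_protein,
        },
        details={"per_gene": per_gene, "empty_output": len(kept) == 0},
    )
    if not kept:
        logger.warning("filter_cna_genes: no gene passed the correlation filter")
    return GeneSet(name="CNA", genes=frozenset(kept), cls="CNA"), report


def nea_context_filter(
    net: GeneNetwork,
    cna_set: GeneSet,
    snv_reference: GeneSet,
    z_threshold: float = 1.96,
    mode: str = "indirect",
    n_perm: int = 50,
    swap_factor: float = 10.0,
    seed: int = 0,
    ensemble: RewiredEnsemble | None = None,
) -> tuple[GeneSet, FilterReport]:
    """Keep CNA genes with enriched connectivity to the SNV reference set.

    Each candidate is tested individually (single-gene NEA, the gene itself
    excluded from the reference); genes with ``z > z_threshold`` survive.
    Candidates absent from the network are dropped.  The per-gene z-scores
    are recorded in the report so the caller can build contingency tables
    over alternative filters.
    """
    ref = GeneSet(name=snv_reference.name, genes=snv_reference.genes & net.nodes, cls=snv_reference.cls)
    if not ref.genes:
        raise ValueError("SNV reference set has no genes in the network")
    if ensemble is None:
        ensemble = RewiredEnsemble(net, n_perm=n_perm, swap_factor=swap_factor, seed=seed)
    kept: list[str] = []
    per_gene: dict[str, dict] = {}
    for gene in sorted(cna_set.genes):
        if gene not in net.nodes:
            per_gene[gene] = {"in_network": False, "z": None, "n_obs": None, "kept": False}
            continue
        rest = ref.genes - {gene}
        if not rest:
            per_gene[gene] = {"in_network": True, "z": None, "n_obs": None, "kept": False}
            continue
        res = nea_single_gene(net, gene, ref, mode=mode, ensemble=ensemble)
        keep = bool(np.isfinite(res.z) and res.z > z_threshold) or res.z == float("inf")
        per_gene[gene] = {
            "in_network": True,
            "z": None if not np.isfinite(res.z) else float(res.z),
            "n_obs": res.n_obs,
            "kept": keep,
        }
        if keep:
            kept.append(gene)
    report = FilterReport(
        stage="nea_context_filter",
        n_in=len(cna_set.genes),
        n_out=len(kept),
        params={"z_threshold": z_threshold, "mode": mode, "n_perm": ensemble.n_perm},
        details={"per_gene": per_gene, "reference_size": len(ref.genes)},
    )
    return GeneSet(name=cna_set.name, genes=frozenset(kept), cls="CNA"), report


def call_allelic_imbalance(
    variants: Sequence[VariantRecord],
    dna_af_band: tuple[float, float] = (0.3, 0.7),
    rna_af_hom: float = 0.95,
    min_depth: int = 10,
) -> tuple[GeneSet, FilterReport]:
    """Call allelically imbalanced genes: heterozygous DNA, monoallelic RNA.

    A variant supports allelic imbalance when its DNA allele fraction lies
    inside ``dna_af_band``, its RNA allele fraction is at least
    ``rna_af_hom`` (or at most ``1 - rna_af_hom``), and both depths reach
    ``min_depth``.  A gene is called imbalanced when at least one of its
    variants is supporting.  Zero-depth records are skipped with a warning.
    """
    lo, hi = dna_af_band
    evidence: dict[str, list[str]] = {}
    n_support = 0
    for v in variants:
        if v.dna_depth == 0 or v.rna_depth == 0:
            warnings.warn(f"skipping zero-depth variant {v.chrom}:{v.pos} ({v.gene})")
            continue
        if v.dna_depth < min_depth or v.rna_depth < min_depth:
            continue
        dna_af = v.dna_af
        rna_af = v.rna_af
        if not (lo <= dna_af <= hi):
            continue
        if not (rna_af >= rna_af_hom or rna_af <= 1.0 - rna_af_hom):
            continue
        evidence.setdefault(v.gene, []).append(f"{v.chrom}:{v.pos}")
        n_support += 1
    genes = frozenset(evidence)
    report = FilterReport(
        stage="call_allelic_imbalance",
        n_in=len(variants),
        n_out=n_support,
        params={"dna_af_band": list(dna_af_band), "rna_af_hom": rna_af_hom, "min_depth": min_depth},
        details={"per_gene_evidence": {g: evidence[g] for g in sorted(evidence)}},
    )
    return GeneSet(name="AI", genes=genes, cls="AI"), report


def filter_snvs(
    variants: Sequence[VariantRecord],
    require_damaging: bool = True,
    min_dna_af: float = 0.2,
) -> tuple[GeneSet, FilterReport]:
    """Build the SNV-impaired gene set from annotated variants.

    Drops common polymorphisms, then variants whose DNA allele fraction is
    below ``min_dna_af`` (an approximation of the subclonal-heterogeneity
    filter), then (when ``require_damaging``) variants not flagged as
    damaging by the external predictor.  Surviving variants are collapsed
    to their gene symbols.
    """
    stage_counts = {"input": len(variants)}
    survivors = [v for v in variants if not v.common_polymorphism]
    stage_counts["after_polymorphism"] = len(survivors)

    kept_af = []
    for v in survivors:
        if v.dna_depth == 0:
            warnings.warn(f"skipping zero-DNA-depth variant {v.chrom}:{v.pos} ({v.gene})")
            continue
        if v.dna_af >= min_dna_af:
            kept_af.append(v)
    survivors = kept_af
    stage_counts["after_heterogeneity"] = len(survivors)

    if require_damaging:
        survivors = [v for v in survivors if v.damaging]
    stage_counts["after_damaging"] = len(survivors)

    genes = frozenset(v.gene for v in survivors)
    report = FilterReport(
        stage="filter_snvs",
        n_in=len(variants),
        n_out=len(survivors),
        params={"require_damaging": require_damaging, "min_dna_af": min_dna_af},
        details={"stage_counts": stage_counts, "n_genes": len(genes)},
    )
    return GeneSet(name="SNV", genes=genes, cls="SNV"), report


def build_ags(
    snv: GeneSet | None = None,
    cna: GeneSet | None = None,
    ai: GeneSet | None = None,
) -> list[GeneSet]:
    """Assemble the per-class altered gene sets plus their union.

    Empty or missing classes are skipped; at least one class must be
    non-empty.
    """
    parts = [s for s in (snv, cna, ai) if s is not None and len(s.genes) > 0]
    if not parts:
        raise ValueError("all alteration classes are empty")
    union = frozenset().union(*(s.genes for s in parts))
    out = list(parts)
    out.append(GeneSet(name="UNION", genes=union, cls="custom"))
    return out
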