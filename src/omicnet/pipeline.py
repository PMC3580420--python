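"""End-to-end orchestration: filters -> AGS assembly -> NEA/GSEA -> reports.

A single declarative config drives the whole workflow.  All randomness
flows from one master seed, expanded with fixed per-stage offsets that are
recorded in the report; reruns of the same config produce byte-identical
result tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .network import (
    GeneNetwork,
    GeneSet,
    load_edge_list,
    load_gmt,
    merge_networks,
    restrict_to_network,
)
from .nea import nea_matrix, results_to_frame
from .gsea import hypergeom_test, adjust_overlap_results, compare_nea_gsea, AgreementTable
from .omics import (
    FilterReport,
    load_omics_table,
    load_variants_tsv,
    load_variants_vcf,
    filter_snvs,
    call_allelic_imbalance,
    filter_cna_genes,
    nea_context_filter,
    build_ags,
)
from .randomize import RewiredEnsemble

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

# fixed per-stage seed offsets (recorded in the report metadata)
_SEED_OFFSETS = {"ensemble": 0, "fdr": 1}


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Relative paths are resolved against ``base_dir`` (the config file's
    directory when loaded from YAML).
    """

    networks: list[str]
    gmt: str
    omics: str
    variants: str
    cna_genes: str
    outdir: str = "pipeline_out"
    base_dir: str = "."
    seed: int = 0
    n_perm: int = 50
    swap_factor: float = 10.0
    min_score: float | None = None
    corr_threshold: float = 0.8
    rpkm_min: float = 1.0
    use_protein: bool = True
    z_threshold: float = 1.96
    context_mode: str = "indirect"
    matrix_mode: str = "direct"
    dna_af_band: tuple[float, float] = (0.3, 0.7)
    rna_af_hom: float = 0.95
    min_depth: int = 10
    min_dna_af: float = 0.2
    require_damaging: bool = True
    p_threshold: float = 0.05
    fdr_threshold: float = 0.10
    fdr_method: str = "left_tail"
    gsea_q_threshold: float = 0.05
    damaging_genes: str | None = None
    polymorphism_sites: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if self.swap_factor <= 0:
            raise ValueError("swap_factor must be positive")
        lo, hi = self.dna_af_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("dna_af_band must satisfy 0 <= lo <= hi <= 1")
        if not (0.5 <= self.rna_af_hom <= 1.0):
            raise ValueError("rna_af_hom must be in [0.5, 1]")

    def resolve(self, path: str) -> Path:
        p = Path(path)
        return p if p.is_absolute() else Path(self.base_dir) / p

    @classmethod
    def from_yaml(cls, path, outdir: str | None = None) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        data.setdefault("base_dir", str(path.parent))
        if "dna_af_band" in data:
            data["dna_af_band"] = tuple(data["dna_af_band"])
        if outdir is not None:
            data["outdir"] = outdir
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for p in list(cfg.networks) + [cfg.gmt, cfg.omics, cfg.variants, cfg.cna_genes]:
            if not cfg.resolve(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")
        return cfg


@dataclass
class PipelineReport:
    """All per-stage reports and summary tables of one run."""

    filter_reports: list[FilterReport] = field(default_factory=list)
    ags_sets: dict[str, list[str]] = field(default_factory=dict)
    contingency: dict[str, int] = field(default_factory=dict)
    agreement: AgreementTable | None = None
    nea_table: list[dict] = field(default_factory=list)
    gsea_table: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "filter_reports": [r.as_dict() for r in self.filter_reports],
            "ags_sets": self.ags_sets,
            "contingency": self.contingency,
            "agreement": None if self.agreement is None else self.agreement.as_dict(),
            "nea_results": self.nea_table,
            "gsea_results": self.gsea_table,
        }

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise PipelineError(name, exc) from exc
    timings[name] = time.perf_counter() - t0
    return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and write tables into ``config.outdir``.

    Stages: merge networks -> SNV filter -> allelic-imbalance calling ->
    CNA correlation filter -> NEA context filter -> AGS assembly ->
    NEA matrix + GSEA + agreement table -> report.
    """
    timings: dict[str, float] = {}
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- load inputs -----------------------------------------------------
    def _load_networks():
        nets = [load_edge_list(config.resolve(p), min_score=config.min_score) for p in config.networks]
        return merge_networks(nets)

    net = _stage("merge_networks", timings, _load_networks)
    fgs_collection = _stage("load_gmt", timings, load_gmt, config.resolve(config.gmt))
    omics = _stage("load_omics", timings, load_omics_table, config.resolve(config.omics))

    def _load_variants():
        vpath = config.resolve(config.variants)
        dmg = None
        poly = None
        if config.damaging_genes:
            dmg = [
                line.strip()
                for line in open(config.resolve(config.damaging_genes), encoding="utf-8")
                if line.strip()
            ]
        if config.polymorphism_sites:
            poly = []
            for line in open(config.resolve(config.polymorphism_sites), encoding="utf-8"):
                if line.strip():
                    chrom, p = line.split()[:2]
                    poly.append((chrom, int(p)))
        if str(vpath).endswith(".vcf"):
            if dmg or poly:
                raise ValueError("external annotation lists are only supported with TSV variants")
            return load_variants_vcf(vpath)
        return load_variants_tsv(vpath, damaging_genes=dmg, polymorphism_sites=poly)

    variants = _stage("load_variants", timings, _load_variants)

    def _load_cna_list():
        with open(config.resolve(config.cna_genes), encoding="utf-8") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        if not genes:
            raise ValueError("CNA candidate list is empty")
        return genes

    cna_candidates = _stage("load_cna_genes", timings, _load_cna_list)

    report = PipelineReport()
    report.metadata = {
        "version": __version__,
        "seed": config.seed,
        "seed_offsets": dict(_SEED_OFFSETS),
        "n_perm": config.n_perm,
        "swap_factor": config.swap_factor,
        "network_nodes": net.n_nodes,
        "network_edges": net.n_edges,
        "n_fgs": len(fgs_collection),
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("base_dir", "outdir")
        },
    }

    # ---- alteration filters ---------------------------------------------
    snv_set, snv_report = _stage(
        "filter_snvs",
        timings,
        filter_snvs,
        variants,
        require_damaging=config.require_damaging,
        min_dna_af=config.min_dna_af,
    )
    report.filter_reports.append(snv_report)

    ai_set, ai_report = _stage(
        "call_allelic_imbalance",
        timings,
        call_allelic_imbalance,
        variants,
        dna_af_band=config.dna_af_band,
        rna_af_hom=config.rna_af_hom,
        min_depth=config.min_depth,
    )
    report.filter_reports.append(ai_report)

    cna_corr_set, corr_report = _stage(
        "filter_cna_genes",
        timings,
        filter_cna_genes,
        omics,
        cna_candidates,
        corr_threshold=config.corr_threshold,
        rpkm_min=config.rpkm_min,
        use_protein=config.use_protein,
    )
    report.filter_reports.append(corr_report)

    # ---- NEA context filter (on ALL candidates, for the contingency) -----
    def _context():
        snv_ref = restrict_to_network(snv_set, net)
        ensemble = RewiredEnsemble(
            net,
            n_perm=config.n_perm,
            swap_factor=config.swap_factor,
            seed=config.seed + _SEED_OFFSETS["ensemble"],
        )
        all_candidates = GeneSet(name="CNA_candidates", genes=frozenset(cna_candidates), cls="CNA")
        nea_all, ctx_report = nea_context_filter(
            net,
            all_candidates,
            snv_ref,
            z_threshold=config.z_threshold,
            mode=config.context_mode,
            ensemble=ensemble,
        )
        return nea_all, ctx_report, ensemble

    nea_pos_set, ctx_report, ensemble = _stage("nea_context_filter", timings, _context)
    report.filter_reports.append(ctx_report)

    corr_pos = cna_corr_set.genes
    nea_pos = nea_pos_set.genes
    contingency = {
        "corr+/nea+": len([g for g in cna_candidates if g in corr_pos and g in nea_pos]),
        "corr+/nea-": len([g for g in cna_candidates if g in corr_pos and g not in nea_pos]),
        "corr-/nea+": len([g for g in cna_candidates if g not in corr_pos and g in nea_pos]),
        "corr-/nea-": len([g for g in cna_candidates if g not in corr_pos and g not in nea_pos]),
    }
    report.contingency = contingency

    cna_final = GeneSet(name="CNA", genes=corr_pos & nea_pos, cls="CNA")
    report.filter_reports.append(
        FilterReport(
            stage="cna_combined",
            n_in=len(cna_candidates),
            n_out=len(cna_final.genes),
            params={"corr_threshold": config.corr_threshold, "z_threshold": config.z_threshold},
            details={"kept": sorted(cna_final.genes)},
        )
    )

    # ---- AGS assembly and set-vs-set analyses ----------------------------
    ags_list = _stage("build_ags", timings, build_ags, snv_set, cna_final, ai_set)
    report.ags_sets = {s.name: sorted(s.genes) for s in ags_list}

    fgs_list = list(fgs_collection)

    def _nea():
        return nea_matrix(
            net,
            ags_list,
            fgs_list,
            mode=config.matrix_mode,
            n_perm=config.n_perm,
            swap_factor=config.swap_factor,
            seed=config.seed + _SEED_OFFSETS["ensemble"],
            include_ags_vs_ags=True,
            fdr_method=config.fdr_method,
            p_threshold=config.p_threshold,
            fdr_threshold=config.fdr_threshold,
        )
    nea_results = _stage("nea_matrix", timings, _nea)

    def _gsea():
        universe = net.nodes | set(fgs_collection.universe)
        for s in ags_list:
            universe |= s.genes
        out = [hypergeom_test(a, f, universe) for a in ags_list for f in fgs_list]
        return adjust_overlap_results(out)

    gsea_results = _stage("gsea", timings, _gsea)

    def _compare():
        pair_results = [r for r in nea_results if r.fgs.cls == "FGS"]
        return compare_nea_gsea(
            pair_results,
            gsea_results,
            nea_threshold=config.p_threshold,
            gsea_threshold=config.gsea_q_threshold,
            nea_fdr_threshold=config.fdr_threshold,
        )

    report.agreement = _stage("compare_nea_gsea", timings, _compare)
    report.nea_table = [r.as_dict() for r in nea_results]
    report.gsea_table = [r.as_dict() for r in gsea_results]

    # ---- outputs ---------------------------------------------------------
    nea_df = results_to_frame(nea_results)
    nea_df.to_csv(outdir / "nea_results.tsv", sep="\t", index=False, float_format="%.6g")
    import pandas as pd

    pd.DataFrame([r.as_dict() for r in gsea_results]).to_csv(
        outdir / "gsea_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    report.to_json(outdir / "report.json")
    with open(outdir / "run.log", "wt", encoding="utf-8") as fh:
        for stage, dt in timings.items():
            fh.write(f"{stage}\t{dt:.3f}s\n")
    for stage, dt in timings.items():
        logger.info("stage %-24s %.3fs", stage, dt)
    return report
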