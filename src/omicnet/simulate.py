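"""Synthetic data with planted ground truth.

Generators for (a) scale-free-ish networks with planted densely connected
modules, (b) cross-line omics tables in which copy number drives expression
and, attenuated, protein abundance, and (c) SNV tables with DNA/RNA allele
depths and planted monoallelic (allelically imbalanced) genes.  Every
generator is deterministic under a fixed seed and returns a
:class:`TruthTable` that records what was planted.

Default omics parameters are calibrated so that the within-line gene-wise
mRNA-protein Spearman correlation lands in the 0.55-0.61 band and the
protein response to copy number is weaker than the mRNA response.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import GeneNetwork, GeneSet, FgsCollection, write_edge_list, write_gmt
from .omics import OmicsTable, VariantRecord, write_variants_tsv

__all__ = [
    "TruthTable",
    "simulate_network",
    "simulate_omics",
    "simulate_variants",
    "simulate_bundle",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class TruthTable:
    """Planted ground truth accompanying a synthetic dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    modules: dict[str, list[str]] = field(default_factory=dict)
    drivers: list[str] = field(default_factory=list)
    snv_genes: list[str] = field(default_factory=list)
    ai_genes: list[str] = field(default_factory=list)
    cn_effect: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path, "rt", encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


def simulate_network(
    n_genes: int = 500,
    background_edge_prob: float = 0.01,
    modules: tuple[tuple[int, float], ...] = ((40, 0.25),),
    seed: int = 0,
) -> tuple[GeneNetwork, TruthTable]:
    """Erdos-Renyi background with planted densely connected modules.

    ``modules`` is a list of ``(size, within_prob)`` pairs; module members
    are drawn disjointly at random and their internal pairs get an extra
    chance ``within_prob`` of being linked (union with the background).
    """
    if not (0.0 <= background_edge_prob <= 1.0):
        raise ValueError("background_edge_prob must be in [0, 1]")
    for size, p in modules:
        if not (0.0 <= p <= 1.0):
            raise ValueError("module within_prob must be in [0, 1]")
        if size < 2:
            raise ValueError("module size must be >= 2")
    if sum(size for size, _ in modules) > n_genes:
        raise ValueError("module sizes exceed n_genes")

    rng = np.random.default_rng([int(seed), 101])
    names = _gene_names(n_genes)
    perm = rng.permutation(n_genes)

    net = GeneNetwork()
    for g in names:
        net.add_node(g)

    # background edges over the upper triangle
    iu, ju = np.triu_indices(n_genes, k=1)
    hit = rng.random(iu.shape[0]) < background_edge_prob
    for a, b in zip(iu[hit], ju[hit]):
        net.add_edge(names[int(a)], names[int(b)])

    module_members: dict[str, list[str]] = {}
    offset = 0
    for mi, (size, within_prob) in enumerate(modules):
        idx = perm[offset : offset + size]
        offset += size
        members = sorted(names[int(i)] for i in idx)
        module_members[f"M{mi + 1}"] = members
        mi_, mj_ = np.triu_indices(size, k=1)
        mhit = rng.random(mi_.shape[0]) < within_prob
        for a, b in zip(mi_[mhit], mj_[mhit]):
            net.add_edge(members[int(a)], members[int(b)])

    truth = TruthTable(
        seed=int(seed),
        params={
            "n_genes": n_genes,
            "background_edge_prob": background_edge_prob,
            "modules": [list(m) for m in modules],
        },
        modules=module_members,
    )
    return net, truth


def simulate_omics(
    n_genes: int = 2000,
    lines: tuple[str, ...] = ("L1", "L2", "L3"),
    cn_states: tuple[int, ...] = tuple(range(9)),
    cn_effect: float = 1.0,
    protein_attenuation: float = 0.7,
    noise_sd: float = 0.5,
    protein_noise_sd: float = 1.1,
    responsive_fraction: float = 1.0,
    protein_missing_rate: float = 0.0,
    seed: int = 0,
    genes: list[str] | None = None,
) -> tuple[OmicsTable, TruthTable]:
    """Copy-number-driven expression with attenuated propagation to protein.

    Per gene g and line l::

        ln RPKM    = b_g + e_g * ln((cn + 0.5) / 2.5) + N(0, noise_sd)
        ln protein = attenuation * (b_g + e_g * ln((cn + 0.5) / 2.5))
                     + N(0, protein_noise_sd)

    with baseline ``b_g ~ N(1.5, 1)`` (log-normal RPKM magnitudes, so that
    RPKM floors have an effect) and ``e_g = cn_effect`` for a
    ``responsive_fraction`` of genes, 0 otherwise.  The defaults are
    calibrated to the 0.55-0.61 mRNA-protein Spearman band.
    """
    if len(lines) < 3:
        raise ValueError("need >= 3 cell lines for cross-line correlations")
    if cn_effect < 0:
        raise ValueError("cn_effect must be >= 0")
    if not (0.0 <= protein_attenuation <= 1.0):
        raise ValueError("protein_attenuation must be in [0, 1]")
    if not (0.0 <= responsive_fraction <= 1.0):
        raise ValueError("responsive_fraction must be in [0, 1]")
    if not (0.0 <= protein_missing_rate <= 1.0):
        raise ValueError("protein_missing_rate must be in [0, 1]")
    if noise_sd < 0 or protein_noise_sd < 0:
        raise ValueError("noise sds must be >= 0")
    if min(cn_states) < 0:
        raise ValueError("copy-number states must be >= 0")

    rng = np.random.default_rng([int(seed), 202])
    if genes is None:
        genes = _gene_names(n_genes, prefix="G")
    else:
        n_genes = len(genes)
    L = len(lines)

    baseline = rng.normal(1.5, 1.0, size=n_genes)
    n_resp = int(round(responsive_fraction * n_genes))
    responsive = np.zeros(n_genes, dtype=bool)
    responsive[rng.choice(n_genes, size=n_resp, replace=False)] = True
    eff = np.where(responsive, cn_effect, 0.0)

    cn = rng.choice(np.asarray(cn_states), size=(n_genes, L))
    dose = np.log((cn + 0.5) / 2.5)
    ln_rpkm = baseline[:, None] + eff[:, None] * dose + rng.normal(0.0, noise_sd, size=(n_genes, L))
    ln_prot = protein_attenuation * (baseline[:, None] + eff[:, None] * dose) + rng.normal(
        0.0, protein_noise_sd, size=(n_genes, L)
    )
    protein = np.exp(ln_prot)
    if protein_missing_rate > 0:
        miss = rng.random(size=(n_genes, L)) < protein_missing_rate
        protein = np.where(miss, np.nan, protein)

    rows = []
    for gi, g in enumerate(genes):
        for li, line in enumerate(lines):
            rows.append(
                {
                    "gene": g,
                    "line": line,
                    "copy_number": int(cn[gi, li]),
                    "rpkm": float(np.exp(ln_rpkm[gi, li])),
                    "protein": float(protein[gi, li]),
                }
            )
    table = OmicsTable(pd.DataFrame(rows))
    truth = TruthTable(
        seed=int(seed),
        params={
            "n_genes": n_genes,
            "lines": list(lines),
            "cn_states": list(int(c) for c in cn_states),
            "cn_effect": cn_effect,
            "protein_attenuation": protein_attenuation,
            "noise_sd": noise_sd,
            "protein_noise_sd": protein_noise_sd,
            "responsive_fraction": responsive_fraction,
            "protein_missing_rate": protein_missing_rate,
        },
        cn_effect={g: float(e) for g, e in zip(genes, eff)},
    )
    return table, truth


def simulate_variants(
    n_sites: int = 2000,
    genes: list[str] | None = None,
    ai_fraction: float = 0.1,
    depth_mean: float = 50.0,
    rna_hom_p: float = 0.98,
    damaging_rate: float = 0.3,
    polymorphism_rate: float = 0.2,
    seed: int = 0,
) -> tuple[list[VariantRecord], TruthTable]:
    """Heterozygous DNA sites with optionally monoallelic RNA expression.

    All sites are heterozygous at the DNA level (alt depth binomial at
    allele fraction 0.5).  Genes planted as allelically imbalanced express
    essentially one allele in RNA (binomial at ``rna_hom_p`` or
    ``1 - rna_hom_p``, one direction per gene); balanced genes stay at 0.5.
    Damaging / common-polymorphism flags are assigned at the given rates.
    """
    if not (0.0 <= ai_fraction <= 1.0):
        raise ValueError("ai_fraction must be in [0, 1]")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    rng = np.random.default_rng([int(seed), 303])
    if genes is None:
        genes = _gene_names(max(1, n_sites // 3), prefix="V")
    n_genes = len(genes)
    n_ai = int(round(ai_fraction * n_genes))
    ai_idx = rng.choice(n_genes, size=n_ai, replace=False)
    ai_mask = np.zeros(n_genes, dtype=bool)
    ai_mask[ai_idx] = True
    # one fixed over-expressed allele direction per AI gene
    ai_high_alt = rng.random(n_genes) < 0.5

    gene_of_site = rng.integers(0, n_genes, size=n_sites)
    out: list[VariantRecord] = []
    for s in range(n_sites):
        gi = int(gene_of_site[s])
        dna_depth = max(1, int(rng.poisson(depth_mean)))
        rna_depth = max(1, int(rng.poisson(depth_mean)))
        dna_alt = int(rng.binomial(dna_depth, 0.5))
        if ai_mask[gi]:
            p = rna_hom_p if ai_high_alt[gi] else 1.0 - rna_hom_p
        else:
            p = 0.5
        rna_alt = int(rng.binomial(rna_depth, p))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        out.append(
            VariantRecord(
                chrom="chr1",
                pos=1000 + 10 * s,
                ref=_BASES[int(ref)],
                alt=_BASES[int(alt)],
                gene=genes[gi],
                dna_depth=dna_depth,
                dna_alt_depth=dna_alt,
                rna_depth=rna_depth,
                rna_alt_depth=rna_alt,
                damaging=bool(rng.random() < damaging_rate),
                common_polymorphism=bool(rng.random() < polymorphism_rate),
            )
        )
    # planted = marked AI *and* carrying at least one site in the output;
    # a gene without any heterozygous site has no imbalance to express
    covered = {genes[int(g)] for g in set(gene_of_site.tolist())}
    ai_genes = sorted(g for i, g in enumerate(genes) if ai_mask[i] and g in covered)
    truth = TruthTable(
        seed=int(seed),
        params={
            "n_sites": n_sites,
            "n_genes": n_genes,
            "ai_fraction": ai_fraction,
            "depth_mean": depth_mean,
            "rna_hom_p": rna_hom_p,
            "damaging_rate": damaging_rate,
            "polymorphism_rate": polymorphism_rate,
        },
        ai_genes=ai_genes,
    )
    return out, truth


# ---------------------------------------------------------------------------
# Coherent bundle for the end-to-end pipeline
# ---------------------------------------------------------------------------


def simulate_bundle(
    outdir,
    seed: int = 7,
    n_genes: int = 300,
    background_edge_prob: float = 0.01,
    module_size: int = 50,
    module_within_prob: float = 0.3,
    n_snv_genes: int = 15,
    n_drivers: int = 12,
    n_offmodule_responsive: int = 12,
    n_nonresponsive: int = 8,
    n_ai_genes: int = 5,
    cn_effect: float = 1.5,
    noise_sd: float = 0.2,
    protein_attenuation: float = 0.8,
    protein_noise_sd: float = 0.3,
) -> tuple[dict[str, Path], TruthTable]:
    """Write a coherent synthetic multi-omics dataset ready for the pipeline.

    Planted structure: one dense network module hosting both the
    SNV-impaired genes and the true CNA drivers; the CNA candidate list
    mixes drivers (copy-number-responsive, in-module), off-module
    responsive decoys (pass the correlation filter, fail the network
    filter) and non-responsive decoys (fail the correlation filter).
    Functional gene sets are the module remainder (connected to, but not
    overlapping, the altered sets) plus random decoy sets.

    Returns the written file paths and the merged truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), 404])

    net, net_truth = simulate_network(
        n_genes=n_genes,
        background_edge_prob=background_edge_prob,
        modules=((module_size, module_within_prob),),
        seed=seed,
    )
    module = list(net_truth.modules["M1"])
    rng.shuffle(module)
    n_needed = n_snv_genes + n_drivers
    if n_needed + 5 > module_size:
        raise ValueError("module too small for the requested SNV/driver split")
    snv_genes = sorted(module[:n_snv_genes])
    drivers = sorted(module[n_snv_genes : n_snv_genes + n_drivers])
    fgs_pool = sorted(module[n_snv_genes + n_drivers :])

    all_genes = sorted(net.nodes)
    off_module = [g for g in all_genes if g not in set(module)]
    rng.shuffle(off_module)
    offmod_resp = sorted(off_module[:n_offmodule_responsive])
    nonresp = sorted(off_module[n_offmodule_responsive : n_offmodule_responsive + n_nonresponsive])
    ai_genes = sorted(
        off_module[
            n_offmodule_responsive
            + n_nonresponsive : n_offmodule_responsive
            + n_nonresponsive
            + n_ai_genes
        ]
    )
    cna_candidates = sorted(drivers + offmod_resp + nonresp)

    # ---- omics table: 3 lines; candidates get varying copy numbers -------
    lines = ("L1", "L2", "L3")
    responsive = set(drivers) | set(offmod_resp)
    varying = set(cna_candidates)
    baseline = {g: float(rng.normal(2.0, 1.0)) for g in all_genes}
    cn_patterns = [(1, 2, 4), (4, 2, 1), (2, 4, 1), (1, 4, 2), (4, 1, 2), (2, 1, 4)]
    rows = []
    cn_effect_truth = {}
    for g in all_genes:
        if g in varying:
            pattern = cn_patterns[int(rng.integers(0, len(cn_patterns)))]
        else:
            pattern = (2, 2, 2)
        eff = cn_effect if g in responsive else 0.0
        cn_effect_truth[g] = eff
        for line, cn in zip(lines, pattern):
            dose = float(np.log((cn + 0.5) / 2.5))
            ln_rpkm = baseline[g] + eff * dose + float(rng.normal(0.0, noise_sd))
            ln_prot = protein_attenuation * (baseline[g] + eff * dose) + float(
                rng.normal(0.0, protein_noise_sd)
            )
            rows.append(
                {
                    "gene": g,
                    "line": line,
                    "copy_number": int(cn),
                    "rpkm": float(np.exp(ln_rpkm)),
                    "protein": float(np.exp(ln_prot)),
                }
            )
    omics = OmicsTable(pd.DataFrame(rows))

    # ---- variants: damaging SNVs in the module, AI genes, background -----
    variants: list[VariantRecord] = []
    pos = 1000

    def het_site(gene, damaging, common, rna_p=0.5):
        nonlocal pos
        dna_depth = max(1, int(rng.poisson(60)))
        rna_depth = max(1, int(rng.poisson(60)))
        ref, alt = rng.choice(4, size=2, replace=False)
        v = VariantRecord(
            chrom="chr1",
            pos=pos,
            ref=_BASES[int(ref)],
            alt=_BASES[int(alt)],
            gene=gene,
            dna_depth=dna_depth,
            dna_alt_depth=int(rng.binomial(dna_depth, 0.5)),
            rna_depth=rna_depth,
            rna_alt_depth=int(rng.binomial(rna_depth, rna_p)),
            damaging=damaging,
            common_polymorphism=common,
        )
        pos += 10
        return v

    for g in snv_genes:
        variants.append(het_site(g, damaging=True, common=False))
        variants.append(het_site(g, damaging=True, common=False))
    for g in ai_genes:
        variants.append(het_site(g, damaging=False, common=False, rna_p=0.98))
    background_pool = [g for g in off_module if g not in set(ai_genes)][:60]
    for g in background_pool:
        variants.append(
            het_site(
                g,
                damaging=bool(rng.random() < 0.05),
                common=bool(rng.random() < 0.5),
            )
        )

    # ---- functional gene sets -------------------------------------------
    half = len(fgs_pool) // 2
    fgs_sets = [
        GeneSet(name="MODULE_A", genes=frozenset(fgs_pool[:half]), cls="FGS"),
        GeneSet(name="MODULE_B", genes=frozenset(fgs_pool[half:]), cls="FGS"),
    ]
    decoy_pool = [g for g in off_module if g not in set(offmod_resp + nonresp + ai_genes)]
    fgs_sets.append(GeneSet(name="DECOY_A", genes=frozenset(sorted(decoy_pool[:20])), cls="FGS"))
    fgs_sets.append(GeneSet(name="DECOY_B", genes=frozenset(sorted(decoy_pool[20:40])), cls="FGS"))

    # ---- write everything ------------------------------------------------
    paths = {
        "network": outdir / "network.tsv",
        "gmt": outdir / "fgs.gmt",
        "omics": outdir / "omics.tsv",
        "variants": outdir / "variants.tsv",
        "cna_genes": outdir / "cna_candidates.txt",
        "truth": outdir / "truth.json",
        "config": outdir / "pipeline.yaml",
    }
    write_edge_list(net, paths["network"])
    write_gmt(FgsCollection(fgs_sets), paths["gmt"])
    omics.to_tsv(paths["omics"])
    write_variants_tsv(variants, paths["variants"])
    with open(paths["cna_genes"], "wt", encoding="utf-8") as fh:
        for g in cna_candidates:
            fh.write(g + "\n")

    truth = TruthTable(
        seed=int(seed),
        params={
            "n_genes": n_genes,
            "background_edge_prob": background_edge_prob,
            "module_size": module_size,
            "module_within_prob": module_within_prob,
            "cn_effect": cn_effect,
            "noise_sd": noise_sd,
            "protein_attenuation": protein_attenuation,
            "protein_noise_sd": protein_noise_sd,
        },
        modules=net_truth.modules,
        drivers=drivers,
        snv_genes=snv_genes,
        ai_genes=ai_genes,
        cn_effect=cn_effect_truth,
    )
    truth.to_json(paths["truth"])

    config = {
        "networks": ["network.tsv"],
        "gmt": "fgs.gmt",
        "omics": "omics.tsv",
        "variants": "variants.tsv",
        "cna_genes": "cna_candidates.txt",
        "seed": int(seed),
        "n_perm": 50,
        "swap_factor": 10.0,
        "corr_threshold": 0.8,
        "rpkm_min": 1.0,
        "z_threshold": 1.96,
        "context_mode": "indirect",
        "matrix_mode": "direct",
        "dna_af_band": [0.3, 0.7],
        "rna_af_hom": 0.95,
        "min_depth": 10,
        "min_dna_af": 0.2,
        "require_damaging": True,
        "p_threshold": 0.05,
        "fdr_threshold": 0.10,
        "gsea_q_threshold": 0.05,
    }
    with open(paths["config"], "wt", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths, truth
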