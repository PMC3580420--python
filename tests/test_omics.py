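import math

import numpy as np
import pandas as pd
import pytest

from omicnet import (
    GeneSet,
    build_ags,
    call_allelic_imbalance,
    cn_expression_association,
    filter_cna_genes,
    filter_snvs,
    mrna_protein_correlation,
    nea_context_filter,
    per_gene_cross_line_correlation,
    permutation_log_ratio,
    simulate_network,
    simulate_omics,
)
from omicnet.omics import (
    OmicsTable,
    VariantRecord,
    load_omics_table,
    load_variants_tsv,
    load_variants_vcf,
    write_variants_tsv,
    write_variants_vcf,
)

from conftest import gene_rows, omics_from_rows, variant


class TestOmicsTable:
    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            OmicsTable(pd.DataFrame({"gene": ["g"], "line": ["L1"]}))

    def test_negative_copy_number_rejected(self):
        rows = gene_rows("g1", (-1, 2, 2), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="copy_number"):
            omics_from_rows(rows)

    def test_tsv_round_trip(self, tmp_path, cna_toy_omics):
        p = tmp_path / "omics.tsv"
        cna_toy_omics.to_tsv(p)
        again = load_omics_table(p)
        assert again.genes == cna_toy_omics.genes
        assert again.lines == cna_toy_omics.lines


class TestKruskalWallis:
    def test_identical_response_gives_h_zero(self):
        rows = []
        for i in range(6):
            rows.append((f"g{i}", "L1", i % 3, 7.0, 1.0))
        res = cn_expression_association(omics_from_rows(rows), "L1")
        assert res.h == 0.0
        assert res.p == 1.0

    def test_two_groups_hand_computation(self):
        """Groups {1,2,3} vs {10,20,30} occupy ranks 1-3 and 4-6:
        H = 12/(6*7) * (3*(2-3.5)^2 + 3*(5-3.5)^2) = 27/7."""
        rows = []
        for i, v in enumerate((1.0, 2.0, 3.0)):
            rows.append((f"a{i}", "L1", 2, v, 1.0))
        for i, v in enumerate((10.0, 20.0, 30.0)):
            rows.append((f"b{i}", "L1", 4, v, 1.0))
        res = cn_expression_association(omics_from_rows(rows), "L1")
        assert res.h == pytest.approx(27 / 7)
        assert res.df == 1
        from scipy.stats import chi2

        assert res.p == pytest.approx(chi2.sf(27 / 7, 1))

    def test_single_class_errors(self):
        rows = [(f"g{i}", "L1", 2, float(i), 1.0) for i in range(5)]
        with pytest.raises(ValueError, match="classes"):
            cn_expression_association(omics_from_rows(rows), "L1")

    def test_null_simulation_p_roughly_uniform(self):
        """cn_effect=0: the KW p-value across replicate simulations is not
        concentrated at small values."""
        ps = []
        for rep in range(20):
            omics, _ = simulate_omics(n_genes=120, cn_effect=0.0, seed=300 + rep)
            ps.append(cn_expression_association(omics, "L1").p)
        assert np.mean(ps) > 0.25
        assert min(ps) < 0.9  # and they do vary


class TestSpearmanOps:
    def test_mrna_protein_monotone(self):
        rows = gene_rows("g1", (2, 2, 2), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0))
        rows = [
            (f"g{i}", "L1", 2, float(i + 1), float((i + 1) ** 2)) for i in range(5)
        ]
        assert mrna_protein_correlation(omics_from_rows(rows), "L1") == pytest.approx(1.0)

    def test_mrna_protein_reversed(self):
        rows = [(f"g{i}", "L1", 2, float(i + 1), float(10 - i)) for i in range(5)]
        assert mrna_protein_correlation(omics_from_rows(rows), "L1") == pytest.approx(-1.0)

    def test_mrna_protein_too_few_pairs(self):
        nan = float("nan")
        rows = [("g0", "L1", 2, 1.0, 1.0), ("g1", "L1", 2, 2.0, nan), ("g2", "L1", 2, 3.0, nan)]
        with pytest.raises(ValueError, match="fewer than 3"):
            mrna_protein_correlation(omics_from_rows(rows), "L1")

    def test_cross_line_monotone(self):
        rows = gene_rows("g1", (1, 2, 4), (5.0, 9.0, 20.0), (1.0, 1.0, 1.0))
        assert per_gene_cross_line_correlation(omics_from_rows(rows), "g1") == pytest.approx(1.0)

    def test_cross_line_reversed(self):
        rows = gene_rows("g1", (1, 2, 4), (20.0, 9.0, 5.0), (1.0, 1.0, 1.0))
        assert per_gene_cross_line_correlation(omics_from_rows(rows), "g1") == pytest.approx(-1.0)

    def test_cross_line_tied_cn_undefined(self):
        rows = gene_rows("g1", (2, 2, 2), (5.0, 9.0, 20.0), (1.0, 1.0, 1.0))
        assert math.isnan(per_gene_cross_line_correlation(omics_from_rows(rows), "g1"))

    def test_cross_line_too_few_lines(self):
        rows = gene_rows("g1", (1, 2), (5.0, 9.0), (1.0, 1.0), lines=("L1", "L2"))
        with pytest.raises(ValueError, match="fewer than 3"):
            per_gene_cross_line_correlation(omics_from_rows(rows), "g1")


class TestPermutationLogRatio:
    def test_n_perm_too_small(self):
        omics, _ = simulate_omics(n_genes=100, seed=1)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_log_ratio(omics, n_perm=5)

    def test_noise_curve_near_zero(self):
        omics, _ = simulate_omics(n_genes=400, cn_effect=0.0, seed=9)
        curve = permutation_log_ratio(omics, n_perm=30, seed=9)
        # under pure noise, observed ~ permuted at every threshold
        assert max(abs(v) for v in curve.log_ratio) < 0.5

    def test_signal_curve_positive_and_growing(self):
        omics, _ = simulate_omics(n_genes=400, cn_effect=3.0, noise_sd=0.2, seed=4)
        curve = permutation_log_ratio(omics, n_perm=30, seed=4)
        mid = curve.log_ratio[5:]
        assert all(v > 0 for v in mid)
        assert curve.log_ratio[9] > curve.log_ratio[2]

    def test_too_few_genes(self):
        omics, _ = simulate_omics(n_genes=30, seed=2)
        with pytest.raises(ValueError, match="50 genes"):
            permutation_log_ratio(omics, n_perm=10)


class TestFilterCnaGenes:
    def test_toy_fixture_exact_survivors(self, cna_toy_omics):
        genes = [f"g{i:02d}" for i in range(1, 11)]
        kept, report = filter_cna_genes(cna_toy_omics, genes)
        assert kept.genes == frozenset({"g01", "g03", "g08", "g10"})
        assert kept.cls == "CNA"
        assert report.n_in == 10
        assert report.n_out == 4

    def test_mean_rule_with_protein(self, cna_toy_omics):
        _, report = filter_cna_genes(cna_toy_omics, ["g02"])
        detail = report.details["per_gene"]["g02"]
        assert detail["rho_rpkm"] == pytest.approx(1.0)
        assert detail["rho_protein"] == pytest.approx(0.5)
        assert detail["mean_rho"] == pytest.approx(0.75)
        assert not detail["kept"]

    def test_transcription_only_reading(self, cna_toy_omics):
        kept, _ = filter_cna_genes(cna_toy_omics, [f"g{i:02d}" for i in range(1, 11)], use_protein=False)
        # without protein, g02/g04? g04 has rpkm rho 0.5 -> dropped; g02 rpkm rho 1 -> kept
        assert "g02" in kept.genes
        assert "g09" in kept.genes
        assert "g04" not in kept.genes

    def test_unknown_gene_errors(self, cna_toy_omics):
        with pytest.raises(ValueError, match="absent"):
            filter_cna_genes(cna_toy_omics, ["nope"])

    def test_empty_output_allowed(self, cna_toy_omics):
        kept, report = filter_cna_genes(cna_toy_omics, ["g05"])
        assert len(kept.genes) == 0
        assert report.details["empty_output"]


class TestNeaContextFilter:
    def test_planted_module_genes_kept(self):
        net, truth = simulate_network(n_genes=200, background_edge_prob=0.01, modules=((40, 0.3),), seed=7)
        module = truth.modules["M1"]
        others = sorted(set(net.nodes) - set(module))
        snv_ref = GeneSet("SNV", frozenset(module[:15]), cls="SNV")
        in_module = module[15:20]
        off_module = others[:15]
        cna = GeneSet("CNA", frozenset(in_module + off_module), cls="CNA")
        kept, report = nea_context_filter(net, cna, snv_ref, seed=7)
        assert kept.genes == frozenset(in_module)
        assert report.n_in == 20
        assert report.n_out == 5

    def test_isolated_gene_dropped(self):
        from conftest import make_network

        net = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")], extra_nodes=["iso"])
        cna = GeneSet("CNA", frozenset({"iso"}), cls="CNA")
        ref = GeneSet("SNV", frozenset({"a", "b"}), cls="SNV")
        kept, report = nea_context_filter(net, cna, ref, n_perm=10, seed=0)
        assert len(kept.genes) == 0

    def test_infinite_threshold_empties(self):
        net, truth = simulate_network(n_genes=100, modules=((20, 0.5),), seed=1)
        module = truth.modules["M1"]
        cna = GeneSet("CNA", frozenset(module[10:15]), cls="CNA")
        ref = GeneSet("SNV", frozenset(module[:10]), cls="SNV")
        kept, _ = nea_context_filter(net, cna, ref, z_threshold=float("inf"), n_perm=10, seed=0)
        assert len(kept.genes) == 0

    def test_reference_missing_from_network_errors(self):
        from conftest import make_network

        net = make_network([("a", "b")])
        with pytest.raises(ValueError, match="reference"):
            nea_context_filter(
                net,
                GeneSet("CNA", frozenset({"a"}), cls="CNA"),
                GeneSet("SNV", frozenset({"zzz"}), cls="SNV"),
            )


class TestCallAllelicImbalance:
    def test_het_dna_hom_rna_called(self):
        v = variant("g1", dna_af=0.5, rna_af=1.0, depth=40)
        genes, report = call_allelic_imbalance([v])
        assert genes.genes == frozenset({"g1"})
        assert report.details["per_gene_evidence"]["g1"] == ["chr1:100"]

    def test_balanced_rna_not_called(self):
        v = variant("g1", dna_af=0.5, rna_af=0.55)
        genes, _ = call_allelic_imbalance([v])
        assert len(genes.genes) == 0

    def test_hom_dna_not_called(self):
        v = variant("g1", dna_af=0.95, rna_af=1.0)
        genes, _ = call_allelic_imbalance([v])
        assert len(genes.genes) == 0

    def test_reference_allele_direction_called(self):
        v = variant("g1", dna_af=0.5, rna_af=0.0)
        genes, _ = call_allelic_imbalance([v])
        assert genes.genes == frozenset({"g1"})

    def test_low_depth_ignored(self):
        v = variant("g1", dna_af=0.5, rna_af=1.0, depth=8)
        genes, _ = call_allelic_imbalance([v])
        assert len(genes.genes) == 0

    def test_zero_depth_skipped_with_warning(self):
        v = VariantRecord("chr1", 5, "A", "G", "g1", 0, 0, 10, 10)
        with pytest.warns(UserWarning, match="zero-depth"):
            genes, _ = call_allelic_imbalance([v])
        assert len(genes.genes) == 0


class TestFilterSnvs:
    def test_toy_fixture_exact_gene_set(self, snv_toy_variants):
        genes, report = filter_snvs(snv_toy_variants)
        assert genes.genes == frozenset({"k1", "k2", "k3", "k4", "k5"})
        assert genes.cls == "SNV"
        assert report.details["stage_counts"]["input"] == 12

    def test_common_polymorphism_dropped(self):
        v = variant("g1", dna_af=0.5, damaging=True, common=True)
        genes, _ = filter_snvs([v])
        assert len(genes.genes) == 0

    def test_damaging_not_required(self, snv_toy_variants):
        genes, _ = filter_snvs(snv_toy_variants, require_damaging=False)
        assert "d3" in genes.genes  # non-damaging but clean

    def test_stage_counts_monotone(self, snv_toy_variants):
        _, report = filter_snvs(snv_toy_variants)
        c = report.details["stage_counts"]
        assert c["input"] >= c["after_polymorphism"] >= c["after_heterogeneity"] >= c["after_damaging"]


class TestBuildAgs:
    def test_three_disjoint_sets(self):
        snv = GeneSet("SNV", frozenset({"a", "b", "c"}), cls="SNV")
        cna = GeneSet("CNA", frozenset({"d", "e", "f"}), cls="CNA")
        ai = GeneSet("AI", frozenset({"g", "h", "i"}), cls="AI")
        out = build_ags(snv, cna, ai)
        assert len(out) == 4
        assert out[-1].name == "UNION"
        assert len(out[-1].genes) == 9

    def test_overlap_deduplicated(self):
        snv = GeneSet("SNV", frozenset({"a", "b"}), cls="SNV")
        cna = GeneSet("CNA", frozenset({"b", "c"}), cls="CNA")
        out = build_ags(snv, cna, None)
        assert out[-1].genes == frozenset({"a", "b", "c"})

    def test_single_class(self):
        snv = GeneSet("SNV", frozenset({"a"}), cls="SNV")
        out = build_ags(snv, None, None)
        assert len(out) == 2
        assert out[1].genes == snv.genes

    def test_all_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_ags(None, GeneSet("CNA", frozenset(), cls="CNA"), None)


class TestVariantIO:
    def test_tsv_round_trip(self, tmp_path, snv_toy_variants):
        p = tmp_path / "variants.tsv"
        write_variants_tsv(snv_toy_variants, p)
        again = load_variants_tsv(p)
        assert again == snv_toy_variants

    def test_tsv_external_annotations(self, tmp_path):
        vs = [variant("g1", damaging=False, pos=10), variant("g2", damaging=False, pos=20)]
        p = tmp_path / "variants.tsv"
        write_variants_tsv(vs, p)
        again = load_variants_tsv(p, damaging_genes=["g1"], polymorphism_sites=[("chr1", 20)])
        assert again[0].damaging and not again[0].common_polymorphism
        assert not again[1].damaging and again[1].common_polymorphism

    def test_vcf_round_trip(self, tmp_path, snv_toy_variants):
        p = tmp_path / "variants.vcf"
        write_variants_vcf(snv_toy_variants, p)
        again = load_variants_vcf(p)
        key = lambda v: (v.chrom, v.pos)
        assert sorted(again, key=key) == sorted(snv_toy_variants, key=key)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="alt depth"):
            VariantRecord("chr1", 1, "A", "G", "g", 10, 12, 10, 5)
        with pytest.raises(ValueError, match="depths"):
            VariantRecord("chr1", 1, "A", "G", "g", -1, 0, 10, 5)
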