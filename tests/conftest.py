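import numpy as np
import pandas as pd
import pytest

from omicnet import GeneNetwork, GeneSet
from omicnet.omics import OmicsTable, VariantRecord


def make_network(edge_pairs, extra_nodes=()):
    net = GeneNetwork()
    for g in extra_nodes:
        net.add_node(g)
    for u, v in edge_pairs:
        net.add_edge(u, v)
    return net


@pytest.fixture
def triangle():
    return make_network([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def k4():
    names = ["n1", "n2", "n3", "n4"]
    return make_network([(u, v) for i, u in enumerate(names) for v in names[i + 1 :]])


@pytest.fixture
def k5():
    names = ["n1", "n2", "n3", "n4", "n5"]
    return make_network([(u, v) for i, u in enumerate(names) for v in names[i + 1 :]])


@pytest.fixture
def star_k13():
    """K1,3: the hub-and-three-leaves graph admits no valid double edge swap."""
    return make_network([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


@pytest.fixture
def path_axf():
    return make_network([("a", "x"), ("x", "f")])


@pytest.fixture
def four_cycle_with_chord(tmp_path):
    """TSV fixture: 4-cycle a-b-c-d plus chord a-c (degrees 2,2,3,3)."""
    path = tmp_path / "cycle_chord.tsv"
    rows = ["a\tb", "b\tc", "c\td", "d\ta", "a\tc"]
    path.write_text("#geneA\tgeneB\n" + "\n".join(rows) + "\n")
    return path


def omics_from_rows(rows):
    return OmicsTable(pd.DataFrame(rows, columns=["gene", "line", "copy_number", "rpkm", "protein"]))


def gene_rows(gene, cns, rpkms, proteins, lines=("L1", "L2", "L3")):
    return [
        (gene, line, cn, rpkm, prot)
        for line, cn, rpkm, prot in zip(lines, cns, rpkms, proteins)
    ]


@pytest.fixture
def cna_toy_omics():
    """Ten genes with hand-set cross-line values; exactly 4 pass the default
    CNA filter (mean Spearman > 0.8 and max RPKM >= 1):

    g01 rpkm rho 1, protein rho 1         -> kept
    g02 rpkm rho 1, protein rho 0.5       -> mean 0.75, dropped
    g03 rpkm rho 1, protein missing       -> mean 1, kept
    g04 rpkm rho 0.5, protein rho 1       -> mean 0.75, dropped
    g05 rpkm rho -1                       -> dropped
    g06 both rho 1 but max rpkm 0.5       -> dropped (rpkm_min)
    g07 copy number tied                  -> undefined rho, dropped
    g08 both rho 1                        -> kept
    g09 rpkm rho 1, protein rho -1        -> mean 0, dropped
    g10 both rho 1                        -> kept
    """
    nan = float("nan")
    rows = []
    rows += gene_rows("g01", (1, 2, 4), (5.0, 9.0, 20.0), (1.0, 2.0, 3.0))
    rows += gene_rows("g02", (1, 2, 4), (5.0, 9.0, 20.0), (1.0, 3.0, 2.0))
    rows += gene_rows("g03", (1, 2, 4), (5.0, 9.0, 20.0), (nan, nan, nan))
    rows += gene_rows("g04", (1, 2, 4), (5.0, 20.0, 9.0), (1.0, 2.0, 3.0))
    rows += gene_rows("g05", (1, 2, 4), (20.0, 9.0, 5.0), (3.0, 2.0, 1.0))
    rows += gene_rows("g06", (1, 2, 4), (0.1, 0.3, 0.5), (1.0, 2.0, 3.0))
    rows += gene_rows("g07", (2, 2, 2), (5.0, 9.0, 20.0), (1.0, 2.0, 3.0))
    rows += gene_rows("g08", (1, 2, 4), (2.0, 4.0, 8.0), (1.5, 2.5, 3.5))
    rows += gene_rows("g09", (1, 2, 4), (5.0, 9.0, 20.0), (3.0, 2.0, 1.0))
    rows += gene_rows("g10", (0, 1, 3), (1.0, 6.0, 30.0), (0.5, 1.5, 2.5))
    return omics_from_rows(rows)


def variant(gene, dna_af=0.5, rna_af=0.5, depth=40, damaging=False, common=False, pos=100):
    return VariantRecord(
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="G",
        gene=gene,
        dna_depth=depth,
        dna_alt_depth=int(round(dna_af * depth)),
        rna_depth=depth,
        rna_alt_depth=int(round(rna_af * depth)),
        damaging=damaging,
        common_polymorphism=common,
    )


@pytest.fixture
def snv_toy_variants():
    """Twelve variants; exactly 5 genes survive the default SNV filter
    (drop common polymorphisms, drop DNA AF < 0.2, require damaging)."""
    return [
        variant("k1", dna_af=0.5, damaging=True, pos=1),              # kept
        variant("k2", dna_af=0.4, damaging=True, pos=2),              # kept
        variant("k3", dna_af=0.9, damaging=True, pos=3),              # kept
        variant("k4", dna_af=0.2, damaging=True, pos=4),              # kept (boundary)
        variant("k5", dna_af=0.5, damaging=True, pos=5),              # kept
        variant("d1", dna_af=0.5, damaging=True, common=True, pos=6),  # polymorphism
        variant("d2", dna_af=0.1, damaging=True, pos=7),              # low AF
        variant("d3", dna_af=0.5, damaging=False, pos=8),             # not damaging
        variant("d4", dna_af=0.15, damaging=True, pos=9),             # low AF
        variant("d5", dna_af=0.5, damaging=False, common=True, pos=10),
        variant("k1", dna_af=0.6, damaging=True, pos=11),             # second hit, same gene
        variant("d6", dna_af=0.05, damaging=False, pos=12),
    ]
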