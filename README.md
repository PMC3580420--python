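# omicnet

Network enrichment analysis (NEA) of multi-omics alteration gene sets,
with the genomic filters needed to build those sets and a calibrated
synthetic-data generator so every stage is testable offline.

## What it does

Given a functional gene network, a collection of functional gene sets
(FGS) and per-sample omics data, the package:

1. builds **altered gene sets** (AGS) from three alteration classes —
   damaging SNVs (externally annotated, polymorphism- and allele-fraction
   filtered), copy-number-altered genes whose expression/protein levels
   track their copy number across samples, and allelically imbalanced
   genes (heterozygous DNA, monoallelic RNA);
2. sharpens the copy-number candidates with a **network context filter**:
   each candidate is individually tested for enriched connectivity to the
   SNV-impaired reference set of the same sample;
3. scores AGS-vs-FGS (and AGS-vs-AGS) relations with **NEA**: the observed
   link count between two sets (direct edges, or indirect two-step paths
   through shared neighbors) is compared against a null learned from
   degree-preserving edge-swap randomizations of the network,
   `z = (n_obs − mean_null) / sd_null`, with one-sided P-values and FDR
   estimated from the depletion tail or from degree-matched random sets;
4. runs a classic **hypergeometric GSEA** on the same pairs as a
   comparator and cross-tabulates the two methods' calls.

A deliberate design point: the edge-swap chain counts *proposals* (not
only successful swaps) toward its budget, which makes its stationary
distribution uniform over the fixed-degree-sequence ensemble of simple
graphs — verified against exhaustive enumeration in the test suite.

## CLI

```sh
# generate a synthetic bundle with planted ground truth
omicnet simulate --outdir bundle --seed 7

# run the full workflow (filters -> AGS -> NEA/GSEA -> report)
omicnet pipeline --config bundle/pipeline.yaml --outdir run

# individual pieces
omicnet nea --network bundle/network.tsv --ags ags.gmt --fgs bundle/fgs.gmt \
    --mode direct --n-perm 50 --seed 1 --out nea.tsv
omicnet gsea --ags ags.gmt --fgs bundle/fgs.gmt --out gsea.tsv
omicnet filter-snv --variants bundle/variants.tsv
omicnet call-ai   --variants bundle/variants.tsv
omicnet filter-cna --omics bundle/omics.tsv --cna-genes bundle/cna_candidates.txt
omicnet rewire --network bundle/network.tsv --out rewired.tsv --seed 3
```

File formats: networks are TSV edge lists (`geneA geneB [evidence] [score]`,
`#` headers allowed), gene sets are GMT, omics tables are long-format TSV
(`gene line copy_number rpkm protein`), variants are flat TSV or VCF with
`DNA`/`RNA` samples carrying `AD` fields.  The pipeline writes
`nea_results.tsv`, `gsea_results.tsv` and `report.json` (filter audit
trail, contingency table of the two CNA filters, NEA/GSEA agreement
table) into its output directory; reruns are byte-identical.

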