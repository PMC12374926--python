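# immunosite

Multisite single-cell immune profiling toolkit: from paired single-cell gene
expression (10x-style MTX triplets) and TCR contig tables (CellRanger-VDJ
style CSVs), the package performs

* **QC gating** — PTPRC-positive cells within total-count, feature-count and
  mitochondrial-fraction windows, with per-criterion exclusion bookkeeping;
* **clonotype assembly** — paired CDR3α/CDR3β nucleotide identity from
  productive, high-confidence contigs (UMI-dominant chain per locus);
* **clonal-expansion binning** — unique / rare / small / medium / large /
  hyperexpanded frequency classes over each sample's TCR pool;
* **repertoire statistics** — D50, analytic (hypergeometric) rarefaction,
  pairwise Jaccard overlap;
* **cross-site clone tracking** — top expanded tumor clones tracked into
  blood and liver replicates, with putative viral bystander annotation
  against a VDJdb-style reference;
* **gene-set scoring** — per-cell rank-based recovery-curve AUC and
  single-sample enrichment (ssGSEA-style) scores;
* **tumor-reactivity nomination** — TIL eligibility filtering (Treg / MAIT /
  γδ / cycling exclusion), per-signature top-5% cuts, per-lineage consensus
  intersection, and tracking of consensus clonotypes into premetastatic
  sites;
* **replicate concordance** — cell-type proportion correlation, log-CPM
  pseudobulk correlation and repertoire Jaccard matrices;
* **differential expression** — Wilcoxon rank-sum (exact for small groups)
  with Benjamini–Hochberg adjustment and strict-threshold DEG filtering;
* **synthetic data** — a fully seeded generator of a three-patient,
  five-sample-per-patient study (blood, tumor, three liver replicates) with
  recorded ground truth: negative-binomial expression programs, power-law
  repertoires, planted shared/viral/reactive clones and QC decoy cells.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(QC bookkeeping, binning, D50/rarefaction oracles, AUC/ssGSEA brute-force
oracles, nomination recovery on the synthetic study, concordance ordering,
end-to-end determinism).

## CLI

```bash
# generate a synthetic study (writes MTX triplets, contig CSVs, cell table,
# gene sets, viral reference, ground truth and a pipeline manifest)
immunosite simulate --out study/ --seed 7

# run every stage end to end
immunosite pipeline --manifest study/manifest.yaml --out run/ --seed 7

# individual stages
immunosite qc --mtx m.mtx --features f.tsv --barcodes b.tsv --out qc.json
immunosite repertoire --contigs contigs.csv --cells cells.tsv \
    --sample-id P01_tumor1 --out rep.tsv
immunosite score --mtx m.mtx --features f.tsv --barcodes b.tsv \
    --gene-sets sets.gmt --method auc --out scores.tsv
immunosite dge --mtx m.mtx --features f.tsv --barcodes b.tsv \
    --group-a a.txt --group-b b.txt --out dge.tsv
```

The pipeline writes TSV/JSON reports for every stage plus `run_log.json`
recording all materialized configuration, so a run is reproducible from its
log alone.

## Conventions worth knowing

* QC boundaries are inclusive (exclusion rules are strict inequalities), and
  "total reads" means total UMI counts per cell.
* Clonotype identity is nucleotide-level; viral annotation matches
  amino-acid CDR3β by default (`beta_aa`), with `alpha_or_beta_aa` and
  `paired_aa` modes available.
* A clone of absolute count 1 is "unique" regardless of frequency; all other
  bins are half-open on the right, with frequency ≥ 5% hyperexpanded.
* D50 uses the ≥ half-pool cumulative rule; both the clone count k and the
  percent-of-distinct-clones index are reported.
* The top-5% nomination cut keeps score ties at the threshold, so the set
  may exceed 5%.
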