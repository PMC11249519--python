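# cfsubtype

Fragment-level cfDNA methylome analysis for lung-cancer subtyping:
discovery of subtype-specific methylation markers from tissue bisulfite
fragments, merged-marker feature construction from plasma cfDNA, and an
L2-regularized logistic classifier distinguishing lung adenocarcinoma
(LUAD) from lung squamous cell carcinoma (LUSC), together with marker
validation procedures, copy-number reporting, and a synthetic-data
generator that stands in for the controlled-access cohorts.

## What it does

- **genome digestion** — in-silico MspI (C^CGG) digestion of a genome
  FASTA into the catalog of enriched regions (< 350 bp between adjacent
  cut points) that is the unit of all downstream analysis.
- **marker discovery** — per-region, per-direction search over observed
  fragment alpha values (fraction of methylated CpGs per molecule) for a
  threshold separating the subtypes: fewer than two qualifying other-class
  samples, maximal target-class support, a 20% noncancer-plasma background
  filter, and top-k selection with ties, for each of the four cells
  (LUAD/LUSC x hypo/hyper).
- **features** — per-marker qualifying-read counts normalized by
  genome-wide fragment count (`1e9 * count / total`), size-constrained
  K-means merging of markers (45–55 per cluster), and
  `ln(mean normalized count + 1)` features per merged marker.
- **classification** — scikit-learn logistic regression (L2, `C=0.1`),
  LOOCV / stratified 10-fold with pooled ROC, Mann–Whitney AUC and DeLong
  95% confidence intervals.
- **validation** — fold-change reproducibility in an independent fragment
  cohort, 450K probe-to-region t tests with Benjamini–Hochberg correction,
  and promoter-overlap gene association with an empirical p value against
  500 random gene sets.
- **cna** — gain/loss thresholding of externally supplied log2
  copy-number ratios (±0.3), 9p21.3 (CDKN2A/B–MTAP) loss detection, and
  tumor-fraction-stratified accuracy (detectable ≥ 3%).
- **simulate** — beta-binomial fragment methylomes with planted
  subtype-specific regions, tumor purity / subclonal carrier fraction in
  tissue, and tumor-fraction mixtures in plasma, plus matched beta/TPM
  validation matrices with a ground-truth ledger.

## CLI

```sh
cfsubtype digest --fasta hg19.fa --out regions.bed [--max-len 350] [--drop-N]
cfsubtype simulate --config cohort.yaml --out simdir/
cfsubtype discover --luad luad.tsv --lusc lusc.tsv \
    --background noncancer.tsv --k 2500 --out markers.tsv
cfsubtype features --markers markers.tsv --fragments plasma.tsv \
    --reference tissue.tsv --merged merged.json --out features.csv
cfsubtype classify --features features.csv --labels labels.csv \
    --scheme loocv --out roc.json
cfsubtype validate --markers markers.tsv --independent cohort2.tsv \
    --regions regions.bed --beta beta.csv --beta-meta probes.csv \
    --beta-labels labels.csv --tpm tpm.csv --tpm-labels labels.csv \
    --promoters promoters.bed --out report.json
cfsubtype cna --bins bins.tsv --genes genes.tsv --out cna.json
```

Fragment tables are per-molecule TSVs (`sample_id  region_id  n_cpgs
n_methylated [count]`) with per-sample sidecar lines
(`#sample  <id>  <total_fragments>  <label>  <material>`) carrying the
genome-wide fragment count used as the normalization denominator.

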