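# metatrans

A self-contained toolkit for paired-end metatranscriptomic RNA-Seq analysis
of microbial communities: quality control, rRNA/tRNA sorting, functional
quantification against an annotated gene catalog, 16S taxonomic profiling,
differential-expression statistics, and a mock-community simulation harness
that measures the whole pipeline's detection accuracy as a ROC curve.

It is aimed at microbiome researchers who have paired-end community RNA-Seq
(e.g. 76 bp HiSeq reads of stool samples) and want both of the two views such
data carries: *which taxa are active* (via the 16S rRNA fraction of the reads)
and *which functions are expressed* (via the putative-mRNA fraction mapped to
a gene catalog), plus defensible statistics for comparing conditions.

## The pipeline

Four stages, each usable on its own:

1. **Filtering** — trim terminal N runs and 3' tails below Phred 10, drop
   reads shorter than 30 nt, discard orphaned mates, collapse identical
   reads into representatives carrying a `|copies=N` header tag.
2. **Sorting** — classify read pairs against user-supplied reference sets
   into 16S/18S (SSU), 23S/28S (LSU), 5S and tRNA categories by canonical
   k-mer containment; the unclassified leftover is the potential mRNA.
3. **Functional analysis** — merge overlapping mates (>= 8 bp overlap,
   <= 10% mismatch), call gene fragments as maximal stop-free stretches over
   six frames (>= 60 nt), cluster greedily at >= 95% identity over >= 90% of
   the shorter sequence (cluster size recorded as `|csize=M`), map cluster
   representatives best-hit against the catalog, and accumulate
   `copies x csize`-weighted raw counts per gene, orthologous group and
   functional category.
4. **Taxonomic analysis** — merge the structural-RNA pairs, subsample
   100,000 reads with a single-pass reservoir, pre-cluster at the 97% OTU
   radius, assign Greengenes-style 7-rank lineages by best-hit mapping, and
   build per-rank count tables (per-sample singletons removed, rows sorted
   by mean abundance). Utilities rarefy tables to a common depth (default
   1,952 reads) and filter taxa below a relative-abundance floor (1% or
   0.2%).

For paired designs (before/after samples per subject), differential
expression is the mean-of-log-ratios test: per feature and subject

&nbsp;&nbsp;&nbsp;&nbsp;r_i = log2((after_i + 1) / (before_i + 1))

on median-of-ratios normalized counts, with a two-sided one-sample t test of
the r_i against zero and Benjamini-Hochberg q-values; features with
q < 0.01 and |log2FC| > 1 are called differentially expressed. Friedman's
rank test, permutation-based Spearman correlation and a PCA summary of
log-transformed matrices support the diversity and ordination analyses.

The simulation harness builds mock communities (coding genes drawn 1,000 per
organism, or lineage-labeled 16S-like references), imposes the benchmark
design — 20% of features 4-fold up, 20% 4-fold down in group 2 — draws
negative-binomial counts, synthesizes error-bearing FASTQ reads under an
empirical per-position quality model, and scores each feature by
1 − nominal p (two-sided). Ranking the features against the simulated truth
yields a ROC curve whose AUC summarizes end-to-end detection accuracy.

## Worked example

Simulate a small functional mock community (100 genes, two groups of six
samples), push the reads through the entire pipeline, and test the groups:

```python
from metatrans.simulate_eval import functional_mock_experiment

res = functional_mock_experiment(n_genes=100, n_per_group=6, seed=1)
print(f"AUC: {res.auc:.3f}")
sig = res.de[(res.de.q < 0.01) & (res.de.log2fc.abs() > 1)]
print(sig.sort_values("p").head(3).round(3).to_string(index=False))
```

prints

```
AUC: 0.993
    feature  mean_count  log2fc   p     q
org3_g00030      17.500   1.670 0.0 0.001
org4_g00027      30.083   2.190 0.0 0.005
org2_g00007      15.417   2.283 0.0 0.005
```

An AUC of 0.993 means the 1 − p score ranks almost every truly
differentially expressed gene above the null genes; the table lists the top
selected genes with their raw mean count, estimated log2 fold change
(true values here are ±2) and nominal/adjusted p-values.

The same is available from the shell:

```bash
metatrans simulate --per-org 20 --n1 6 --n2 6 --seed 1 --out-dir sim/
metatrans qc --in1 sim/g1s01_1.fastq --in2 sim/g1s01_2.fastq --out-dir qc/
metatrans evaluate --de de_results.tsv --truth sim/truth.tsv --roc roc.tsv
```

and `metatrans all --config config.yaml` runs every stage for a sample
manifest. The config is flat YAML:

```yaml
samples:
  - {name: stoolA, fastq1: A_1.fastq, fastq2: A_2.fastq}
rrna_refs: {ssu: silva_ssu.fasta, lsu: silva_lsu.fasta}
catalog: gene_catalog.fasta
annotations: annotations.tsv      # gene_id  og_id  ko_id  category
ref16s: greengenes_like.fasta     # headers: >id<TAB>k__...; ...; s__...
out_dir: results
seed: 1
```

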