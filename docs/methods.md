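# Methods

This note records the models, algorithmic choices and defaults behind
`metatrans`, and what the synthetic benchmarks do and do not demonstrate.

## Quality filtering

Reads are trimmed in a fixed order: terminal N runs first, then the maximal
3' suffix whose bases are all below the quality floor (Phred 10 by
default), then an optional user-supplied 3' adapter. Anything shorter than
30 nt afterwards is rejected, and a pair is dropped whenever either mate is
(the surviving singleton is counted as an orphan). Quality trimming is
deliberately suffix-based — scanning from the 3' end, where Illumina
quality decays — rather than windowed; internal low-quality bases and
internal Ns are kept so that masked but otherwise long reads survive.

Identical reads collapse to one representative that keeps the first-seen
id, sums member copy counts into a `|copies=N` header tag, and takes the
per-position maximum quality over members (qualities are bookkeeping here,
not evidence weights; the maximum keeps the representative from being
penalized by its worst member). Pairs are collapsed jointly on the
(mate 1, mate 2) sequence pair so the mate link survives collapsing.

## Overlap merging

Mate 2 is reverse-complemented and slid against mate 1 over every offset,
including read-through placements where the fragment is shorter than a
read. A placement is a candidate when the overlap spans at least 8 bp with
a mismatch fraction at most 10%. Among candidates the longest overlap
wins; ties prefer fewer mismatches, then the smaller offset — declared
explicitly so merging is deterministic. In the overlapped region the
higher-quality base is emitted with the maximum of the two qualities
(mate 1 wins ties). Match counting across all offsets is done with one-hot
cross-correlations, which is exactly equivalent to character comparison;
the test suite checks the equivalence against a brute-force scan on 10,000
random pairs.

## rRNA/tRNA sorting

Rather than a seeded aligner, the sorter uses canonical k-mer containment:
each category's reference FASTA is reduced to a set of canonical 15-mers
(lexicographic minimum of a k-mer and its reverse complement; k-mers with
non-ACGT characters skipped), and a read is scored per category by the
fraction of its canonical k-mers present in that category's set. The
argmax category is assigned when its fraction reaches `min_frac` (default
0.25); ties break by the fixed priority SSU > LSU > 5S > tRNA, and
everything else is potential mRNA. k = 15 makes chance matches against a
few megabases of reference rare (4^15 ≈ 10^9), while 0.25 tolerates a
sequencing-error every ~15 bases; both are exposed as parameters because
they are conventions, not measurements. A pair is condemned by either
mate: sorting happens before merging, and one structural-RNA mate is
sufficient evidence for the fragment.

## Gene fragments

Gene calling on short reads is reduced to its contract — predict or
discard. A fragment is any maximal stop-free codon stretch of at least
60 nt in any of the six frames (standard-code stops TAA/TAG/TGA); reads
yielding none are dropped. Within the pipeline the longest fragment per
read (first on ties) is carried forward, so one read is counted at most
once downstream; for unmerged pairs the two mates share a read id and the
pair likewise contributes a single counted query, mirroring paired-end
mapping where a pair is one observation.

## Greedy clustering

Fragments are sorted by length descending (stable) and each joins the
first existing cluster whose representative aligns at >= 95% identity over
>= 90% of the shorter sequence, else founds a new cluster. The predicate
is evaluated on the best-scoring local alignment (BLAST-like scores:
match +2, mismatch −3, gap open −5, extend −2), with identity = matching
columns / aligned columns and coverage = aligned query span / query
length. Cluster weight is the sum of member copy counts and is written
into the representative's `|csize=M` tag, so read totals are conserved
through collapse → cluster → count; a `members` mode restores plain
cardinality.

A seed prefilter keeps this exact, not approximate: an alignment passing
the predicate has, by pigeonhole over its mismatch/gap budget, an exact
match run long enough to put a guaranteed number of shared 8-mers on a
single ungapped diagonal, and that diagonal must offer enough overlap.
Representatives failing either bound cannot pass the alignment predicate
and are skipped without aligning; the suite verifies exact agreement with
a brute-force all-representatives implementation on 200 sequences.

## Best-hit mapping

Queries are mapped on both strands against a 15-mer seed index of the
catalog. Candidates sharing at least one seed are ranked by seed count
(top 5 aligned); a hit requires >= 90% identity over >= 80% of the query,
and the best hit is chosen by highest identity, then longer alignment,
then lexicographically smallest gene id — "first match" made
deterministic. A full-length exact substring match (identity 100,
coverage 1) short-circuits alignment, since no gapped alignment can beat
it. Local alignment was chosen over end-gap-free glocal alignment so that
queries hanging off a gene end fail on coverage instead of being forced
into spurious mismatches. Counting credits each query's `copies x csize`
to its gene; duplicate hits from one query id are discarded with a
warning. Gene counts roll up by summation to orthologous groups and then
one-letter functional categories, with unannotated features accumulating
under `unknown` so column totals are conserved.

## Taxonomic profiling

Structural-RNA pairs are merged (unmerged pairs contribute mate 1),
subsampled to 100,000 reads with Algorithm R — single-pass, uniform
without replacement, deterministic per seed — and pre-clustered with the
same greedy clusterer at the conventional 97% OTU radius. Cluster
representatives are assigned the lineage of their best 16S hit; reference
headers carry Greengenes-style 7-rank lineages. Rank tables truncate each
lineage at the table's rank, grouping unknown trailing ranks under the
deepest known prefix (producing "unknown Clostridiales"-style features).
After construction, cells equal to 1 are zeroed — per-sample singleton
removal against false-positive assignments — and rows are sorted by mean
abundance descending. Rarefaction draws a multivariate hypergeometric
sample per column (exactly `depth` reads, without replacement), dropping
under-depth samples with a warning rather than failing the run.

## Differential expression

Counts are normalized with median-of-ratios size factors computed on
features nonzero in every sample; when no such feature exists the factors
fall back, with a warning, to counts + 1. The paired test forms
per-subject log2 ratios (after vs before, pseudocount 1 against zeros) and
tests their mean against zero with a two-sided one-sample t test
(`wilcoxon` available as an alternative for the small-n paired design —
t is the default because with four subjects the signed-rank test cannot
reach p < 0.05 at all); q-values are Benjamini-Hochberg. Default selection
is q < 0.01 and |log2FC| > 1.

The mock experiments compare two independent groups, so the harness uses a
Welch t test on log2(normalized + 1). For this test the size factors are
median-of-ratios on counts + 1: at shallow depth the nonzero-in-every-sample
rule would drop most down-regulated features (whose low-group counts hit
zero) while keeping every up-regulated one, skewing the ratio mixture whose
median the factor takes and absorbing a substantial part of the true fold
change into normalization. Including all features via the pseudocount keeps
the 20%/20% design's tails symmetric around the null median, and the
estimated factors of the two groups agree. The reported group log2 fold change
is log2 of the ratio of group mean normalized counts (+ pseudocount)
rather than the difference of log-transformed means: at a mean of ~10
reads per gene the log-transform estimator is shrunk toward zero by the
pseudocount and by Jensen's inequality (≈ 25% attenuation of a true
2.0), while the ratio-of-means estimator is nearly unbiased. The p-value
and the fold-change estimate are therefore decoupled on purpose.

Friedman's test uses within-subject midranks with the tie-corrected
chi-square (df k−1) and offers exact enumeration of all (k!)^n
within-subject rank permutations when that count is at most 10^6. The
chi-square approximation agrees with the exact null to within 0.02 in the
significance region (p <= 0.10); in the body of the discrete null the two
can differ substantially, which is inherent to n = 4 and not an
implementation artifact, so the suite checks agreement where the
approximation is actually used. Permutation Spearman correlation permutes
one vector, uses exact enumeration when n! fits in the permutation budget
and the add-one estimator otherwise (a permutation p is never 0). PCA
operates on log2(normalized + 1), feature-centered, via SVD, with the
sign convention that each component's largest-magnitude loading is
positive.

## Synthetic mock communities

The generator defines the benchmark conditions:

* **Genes** are random stop-free codon strings, 300–1500 nt, drawn 1,000
  per organism from per-organism pools without replacement — stop-free so
  that simulated mRNA reads contain open reading frames, as real coding
  fragments do.
* **Design**: 20% of features 4-fold up and 20% 4-fold down in group 2,
  chosen uniformly; everything else null. Full-scale group sizes default
  to 50 (functional) and 25 (taxonomic) samples.
* **Counts** are negative binomial with mean proportional to gene length
  (default 10 expected read pairs per kb per sample, so a typical ~0.9 kb
  gene yields ~9 pairs) and dispersion φ = 0.2 (var = μ + φμ²), a typical
  RNA-seq overdispersion; φ → 0 recovers Poisson.
* **Reads**: per counted fragment, a clipped-normal fragment length
  (250 ± 25 nt) placed uniformly on the gene; mate 1 reads the 5' end and
  mate 2 the reverse complement of the 3' end, 76 nt each. Per-base
  qualities come from a per-position histogram model — trainable from any
  uniform-length FASTQ, with a flat model and a HiSeq-like profile
  (mean Phred ~38 decaying to ~28) built in — and each base is substituted
  with probability 10^(−q/10). With a 250 nt fragment the mates usually do
  not overlap, so the merge stage mostly passes pairs through unmerged,
  as intended.
* **16S-like references** for the taxonomic mock are generated by
  diversifying one random ~1200 nt ancestor down a 7-rank hierarchy with
  per-split substitution rates (10, 7, 5, 4, 3, 2.5% from phylum to
  species), giving congeneric species ~5% apart — resolvable by best-hit
  mapping yet close enough to exercise the 97% OTU clustering. These are
  synthetic stand-ins; their labels carry no biological meaning.
* **Decontamination**: catalog entries aligning to any simulation source
  at > 90% identity over >= 80% of the shorter sequence can be removed, to
  avoid over-crediting a database that contains the answers.

Scoring follows the benchmark definition: score = 1 − nominal p,
two-sided, so the direction of change never affects the ranking; ROC
curves sweep all score thresholds with the simulated DE features as
positives, and AUC is the trapezoid area (equal to tie-aware pairwise
concordance). Features the pipeline never detects score 0 — they are
counted as misses rather than silently excluded.

The shipped benchmarks run at desk scale: 1,000 genes and two groups of 10
samples (functional), 200 organisms and two groups of 10 (taxonomic).
These sizes keep the full simulate → pipeline → test → ROC loop within
minutes on one CPU while leaving the per-feature read depths and effect
sizes at their full-scale values.

**What passing these benchmarks shows** — that the whole chain (read
simulation, QC, sorting, merging, ORF calling, clustering, mapping,
counting, testing, scoring) preserves a 4-fold signal well enough to rank
DE features far above null ones, and that every bookkeeping invariant
(copy/weight conservation, partitioning, determinism) holds. **What it
does not show**: the synthetic communities have no GC or positional bias,
no indels, no chimeric fragments, no strain-level mixtures, no catalog
incompleteness, and taxa diverge much more uniformly than real 16S
phylogenies; real-data accuracy will be lower and database-dependent.

## Determinism and numerics

Every stochastic step takes an explicit seed; the pipeline driver derives
per-stage seeds from a single global seed by hashing the stage name, so
stages stay independently reproducible. Permutation p-values use the
add-one estimator; BH q-values come from the standard step-up with
monotonicity enforcement; alignment tie-breaks, merge tie-breaks and
best-hit tie-breaks are all total orders. Degenerate inputs are handled
explicitly: empty matrices stay empty, all-zero features test as null
(p = 1), constant vectors are rejected where a correlation or variance is
undefined, and zero-variance nonzero log-ratios are reported as maximal
evidence (p = 0) rather than NaN.
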