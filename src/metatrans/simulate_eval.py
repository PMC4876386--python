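"""Mock-community simulation and ROC validation of the pipeline.

Builds synthetic mock communities (coding genes or lineage-labeled
16S-like references), applies the benchmark differential-expression
design — 20% of features 4-fold up, 20% 4-fold down between two groups —
simulates negative-binomial true counts and 76 bp paired-end reads under
an empirical per-position quality model, pushes the reads through the
full pipeline, scores each feature by 1 - nominal p (two-sided: direction
of change is ignored), and summarizes detection accuracy as a ROC curve
with its AUC.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._align import SeedIndex, local_identity_coverage
from .function_annot import CatalogEntry, CatalogIndex, quantify_functional, aggregate_counts
from .preprocess import MergePolicy, TrimPolicy, collapse_pairs, filter_pairs, merge_sample
from .rna_sort import KmerIndex, RnaCategory, sort_sample
from .seqio import (
    MAX_PHRED,
    AbundanceMatrix,
    SeqRecord,
    read_fastq,
    read_fastq_pairs,
    revcomp,
    write_fastq,
)
from .stats import group_logratio_test
from .taxprofile import Lineage, Reference16S, build_rank_tables, profile_sample

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

UP, DOWN, NULL = "UP", "DOWN", "NULL"


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit sub-seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


# ---------------------------------------------------------------------------
# synthetic sources


def synthesize_coding_genes(
    n: int,
    rng: np.random.Generator,
    min_len: int = 300,
    max_len: int = 1500,
    prefix: str = "gene",
) -> list[SeqRecord]:
    """Random stop-free coding sequences (frame 0), lengths uniform in range.

    Built from the 61 non-stop codons so that simulated reads carry long
    open reading frames, as real mRNA fragments do.
    """
    genes = []
    for i in range(n):
        ncod = int(rng.integers(min_len // 3, max_len // 3 + 1))
        idx = rng.integers(0, len(_NON_STOP_CODONS), size=ncod)
        seq = "".join(_NON_STOP_CODONS[j] for j in idx)
        genes.append(SeqRecord(f"{prefix}{i + 1:05d}", seq))
    return genes


def synthesize_source_genomes(
    n_organisms: int = 5,
    genes_per_organism: int = 2000,
    seed: int = 0,
    min_len: int = 300,
    max_len: int = 1500,
) -> dict[str, list[SeqRecord]]:
    """Per-organism gene pools to draw a mock community from."""
    rng = np.random.default_rng(seed)
    return {
        f"org{k + 1}": synthesize_coding_genes(
            genes_per_organism, rng, min_len, max_len, prefix=f"org{k + 1}_g"
        )
        for k in range(n_organisms)
    }


def build_mock(
    source_genes: Mapping[str, Sequence[SeqRecord]],
    genes_per_org: int = 1000,
    seed: int = 0,
) -> list[SeqRecord]:
    """Draw exactly ``genes_per_org`` genes per organism, without replacement."""
    rng = np.random.default_rng(seed)
    selected: list[SeqRecord] = []
    for organism in source_genes:
        pool = list(source_genes[organism])
        if len(pool) < genes_per_org:
            raise ValueError(
                f"organism {organism!r} supplies {len(pool)} genes, "
                f"need {genes_per_org}"
            )
        picks = rng.choice(len(pool), size=genes_per_org, replace=False)
        selected.extend(pool[int(i)] for i in picks)
    return selected


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    if mask.any():
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.array([idx.get(b, 0) for b in arr[mask]])
        shift = rng.integers(1, 4, size=mask.sum())
        arr[mask] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def synthesize_16s_references(
    n_organisms: int = 200,
    seed: int = 0,
    base_len: int = 1200,
    rank_rates: Sequence[float] = (0.10, 0.07, 0.05, 0.04, 0.03, 0.025),
) -> list[tuple[SeqRecord, Lineage]]:
    """Lineage-labeled 16S-like reference set with controlled divergence.

    A random ancestor sequence is diversified down a 7-rank hierarchy;
    ``rank_rates`` are per-site substitution rates applied at each split
    from phylum to species, so organisms sharing a genus differ by roughly
    twice the species rate.  Every organism gets a unique species name.

    .. note:: synthetic stand-in for a real 16S mock community; labels and
       sequences carry no biological meaning.
    """
    rng = np.random.default_rng(seed)
    root = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=base_len))
    counter = {"n": 0, "node": 0}
    prefixes = ("p__", "c__", "o__", "f__", "g__", "s__")
    out: list[tuple[SeqRecord, Lineage]] = []

    def split(count: int, level: int, seq: str, path: list[str]) -> None:
        if count == 0:
            return
        if level == len(prefixes) - 1:  # species: one organism per leaf
            for _ in range(count):
                counter["n"] += 1
                ident = f"otu{counter['n']:04d}"
                leaf = _mutate(seq, rank_rates[level], rng)
                lineage = Lineage(
                    ("k__Bacteria", *path, f"{prefixes[level]}Sp{counter['n']:04d}")  # type: ignore[arg-type]
                )
                out.append((SeqRecord(ident, leaf), lineage))
            return
        n_children = min(count, int(rng.integers(2, 5)))
        sizes = np.full(n_children, count // n_children)
        sizes[: count % n_children] += 1
        for size in sizes:
            counter["node"] += 1
            child_seq = _mutate(seq, rank_rates[level], rng)
            name = f"{prefixes[level]}Tax{counter['node']:04d}"
            split(int(size), level + 1, child_seq, path + [name])

    split(n_organisms, 0, root, [])
    return out


# ---------------------------------------------------------------------------
# design and counts


@dataclass
class MockDesign:
    """Ground truth of a mock experiment.

    ``labels`` maps gene id to UP/DOWN/NULL; ``fold_change`` holds the
    group-2 multiplier (fold, 1/fold or 1).  Group sizes default to the
    benchmark's functional design (50 + 50 samples); the reduced-scale
    harnesses pass smaller values explicitly.
    """

    genes: list[SeqRecord]
    labels: dict[str, str]
    fold: float = 4.0
    frac_up: float = 0.20
    frac_down: float = 0.20
    n1: int = 50
    n2: int = 50
    mean_per_kb: float = 10.0  # expected read pairs per kb of gene per sample
    dispersion: float = 0.2
    seed: int = 0

    @property
    def fold_change(self) -> dict[str, float]:
        return {
            g: self.fold if lab == UP else (1.0 / self.fold if lab == DOWN else 1.0)
            for g, lab in self.labels.items()
        }

    @property
    def samples(self) -> tuple[list[str], list[str]]:
        g1 = [f"g1s{i + 1:02d}" for i in range(self.n1)]
        g2 = [f"g2s{i + 1:02d}" for i in range(self.n2)]
        return g1, g2

    @property
    def truth(self) -> pd.Series:
        return pd.Series(
            {g: lab != NULL for g, lab in self.labels.items()}, name="is_de"
        )


def assign_de(
    genes: Sequence[SeqRecord],
    frac_up: float = 0.20,
    frac_down: float = 0.20,
    fold: float = 4.0,
    seed: int = 0,
    **design_kwargs,
) -> MockDesign:
    """Label round(frac_up*G) genes UP and round(frac_down*G) genes DOWN.

    The UP and DOWN sets are disjoint and drawn uniformly at random with
    the given seed; everything else is NULL.
    """
    if frac_up + frac_down > 1.0 + 1e-9:
        raise ValueError("frac_up + frac_down must be <= 1")
    rng = np.random.default_rng(seed)
    n = len(genes)
    n_up = round(frac_up * n)
    n_down = round(frac_down * n)
    picks = rng.choice(n, size=n_up + n_down, replace=False)
    labels = {g.id: NULL for g in genes}
    for i in picks[:n_up]:
        labels[genes[int(i)].id] = UP
    for i in picks[n_up:]:
        labels[genes[int(i)].id] = DOWN
    return MockDesign(
        genes=list(genes),
        labels=labels,
        fold=fold,
        frac_up=frac_up,
        frac_down=frac_down,
        seed=seed,
        **design_kwargs,
    )


def simulate_counts(design: MockDesign, seed: int | None = None) -> AbundanceMatrix:
    """Negative-binomial true counts per gene and sample.

    Gene means scale with gene length (``mean_per_kb`` read pairs per kb);
    group-2 means are multiplied by the gene's fold change.  Dispersion phi
    parameterizes var = mu + phi * mu^2; phi -> 0 falls back to Poisson.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    g1, g2 = design.samples
    mu_base = np.array(
        [design.mean_per_kb * len(g.seq) / 1000.0 for g in design.genes]
    )
    fc = np.array([design.fold_change[g.id] for g in design.genes])
    data = {}
    for sample in g1 + g2:
        mu = mu_base * fc if sample in g2 else mu_base
        if design.dispersion < 1e-8:
            counts = rng.poisson(mu)
        else:
            size = 1.0 / design.dispersion
            p = size / (size + mu)
            counts = rng.negative_binomial(size, p)
        data[sample] = counts
    df = pd.DataFrame(data, index=[g.id for g in design.genes])
    return AbundanceMatrix(df)


# ---------------------------------------------------------------------------
# quality model and read simulation


@dataclass
class QualityModel:
    """Per-position Phred histograms of uniform-length reads."""

    read_len: int
    hist: np.ndarray  # (read_len, MAX_PHRED + 1), rows sum to 1

    def __post_init__(self) -> None:
        self.hist = np.asarray(self.hist, dtype=float)
        if self.hist.shape != (self.read_len, MAX_PHRED + 1):
            raise ValueError("histogram shape must be (read_len, 42)")
        sums = self.hist.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("histograms must normalize to 1 per position")

    @classmethod
    def flat(cls, phred: int, read_len: int = 76) -> "QualityModel":
        hist = np.zeros((read_len, MAX_PHRED + 1))
        hist[:, phred] = 1.0
        return cls(read_len, hist)

    @classmethod
    def hiseq_like(cls, read_len: int = 76, q_start: int = 38, q_end: int = 28) -> "QualityModel":
        """Position-decaying profile typical of HiSeq 76 bp runs."""
        hist = np.zeros((read_len, MAX_PHRED + 1))
        means = np.linspace(q_start, q_end, read_len)
        for pos, m in enumerate(means):
            center = int(round(m))
            for dq, w in ((-2, 0.25), (0, 0.50), (2, 0.25)):
                q = int(np.clip(center + dq, 2, MAX_PHRED))
                hist[pos, q] += w
        return cls(read_len, hist)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, read_len) matrix of Phred scores drawn from the model."""
        out = np.empty((n, self.read_len), dtype=np.int64)
        for pos in range(self.read_len):
            out[:, pos] = rng.choice(MAX_PHRED + 1, size=n, p=self.hist[pos])
        return out

    def mean_by_position(self) -> np.ndarray:
        return self.hist @ np.arange(MAX_PHRED + 1)


def train_quality_model(path: str | Path) -> QualityModel:
    """Fit per-position Phred histograms from a FASTQ file."""
    counts: np.ndarray | None = None
    read_len = None
    n = 0
    for rec in read_fastq(path):
        if read_len is None:
            read_len = len(rec.seq)
            counts = np.zeros((read_len, MAX_PHRED + 1))
        if len(rec.seq) != read_len:
            raise ValueError(
                f"mixed read lengths ({len(rec.seq)} vs {read_len}); "
                "the quality model requires uniform length"
            )
        assert counts is not None
        counts[np.arange(read_len), rec.qual] += 1
        n += 1
    if counts is None or n == 0:
        raise ValueError("empty FASTQ: cannot train a quality model")
    return QualityModel(read_len, counts / n)


def _seqs_to_codes(seqs: Sequence[str]) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        lookup[base] = code
    mat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lookup[mat].reshape(len(seqs), -1)


def _codes_to_seqs(codes: np.ndarray) -> list[str]:
    flat = _BASES[codes].tobytes().decode("ascii")
    n, L = codes.shape
    return [flat[i * L : (i + 1) * L] for i in range(n)]


def _apply_errors(
    codes: np.ndarray, quals: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    err_p = np.power(10.0, -quals / 10.0)
    mask = rng.random(codes.shape) < err_p
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum()))
        codes = codes.copy()
        codes[mask] = (codes[mask].astype(np.int64) + shift) % 4
    return codes


def simulate_reads(
    design: MockDesign,
    counts: AbundanceMatrix,
    quality_model: QualityModel,
    out_dir: str | Path,
    read_len: int = 76,
    frag_mean: float = 250.0,
    frag_sd: float = 25.0,
    seed: int = 0,
) -> dict[str, tuple[Path, Path]]:
    """Simulate paired-end FASTQ files matching the true counts.

    Per counted fragment: a clipped-normal fragment length and uniform
    start position on the gene; mate 1 reads the 5' end, mate 2 the
    reverse complement of the 3' end; per-base qualities come from the
    quality model and each base is substituted with probability
    10^(-q/10).  Genes shorter than ``read_len`` are skipped with a
    warning.  Returns {sample: (fastq1, fastq2)}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = {g.id: g.seq for g in design.genes}
    too_short = {gid for gid, seq in genes.items() if len(seq) < read_len}
    if too_short:
        warnings.warn(f"{len(too_short)} genes shorter than read_len skipped")
    paths: dict[str, tuple[Path, Path]] = {}
    df = counts.df
    for sample in counts.samples:
        frags: list[str] = []
        origins: list[str] = []
        for gid, c in df[sample].items():
            c = int(c)
            if c == 0 or gid in too_short:
                continue
            seq = genes[gid]
            lens = np.clip(
                np.rint(rng.normal(frag_mean, frag_sd, size=c)),
                read_len,
                len(seq),
            ).astype(int)
            starts = rng.integers(0, len(seq) - lens + 1)
            for ln, st in zip(lens, starts):
                frags.append(seq[st : st + ln])
                origins.append(gid)
        n = len(frags)
        p1 = out_dir / f"{sample}_1.fastq"
        p2 = out_dir / f"{sample}_2.fastq"
        if n == 0:
            p1.write_text("")
            p2.write_text("")
            paths[sample] = (p1, p2)
            continue
        mate1 = [f[:read_len] for f in frags]
        mate2 = [revcomp(f[-read_len:]) for f in frags]
        records: list[list[SeqRecord]] = []
        for mates in (mate1, mate2):
            codes = _seqs_to_codes(mates)
            quals = quality_model.sample(rng, n)
            codes = _apply_errors(codes, quals, rng)
            seqs = _codes_to_seqs(codes)
            records.append(
                [
                    SeqRecord(f"{origins[i]}.{i + 1}", seqs[i], list(quals[i]))
                    for i in range(n)
                ]
            )
        write_fastq(records[0], p1)
        write_fastq(records[1], p2)
        paths[sample] = (p1, p2)
    return paths


# ---------------------------------------------------------------------------
# reference decontamination


def decontaminate_reference(
    catalog: Sequence[CatalogEntry],
    sources: Sequence[SeqRecord],
    max_id: float = 90.0,
    min_cov: float = 0.80,
    seed_k: int = 15,
) -> tuple[list[CatalogEntry], int]:
    """Remove catalog entries too similar to the simulation source genes.

    An entry is dropped when it aligns to any source at identity
    > ``max_id`` over >= ``min_cov`` of the shorter sequence (prevents
    accuracy overestimates from near-identical database entries).
    Returns (kept entries, number removed).
    """
    index = SeedIndex([s.seq for s in sources], k=seed_k)
    kept: list[CatalogEntry] = []
    removed = 0
    for entry in catalog:
        contaminated = False
        for strand_seq in (entry.seq, revcomp(entry.seq)):
            hits = index.seed_hits(strand_seq)
            for tidx in sorted(hits, key=lambda t: -sum(hits[t].values())):
                source_seq = index.sequences[tidx]
                if len(strand_seq) <= len(source_seq):
                    query, target = strand_seq, source_seq
                else:
                    query, target = source_seq, strand_seq
                identity, coverage, _ = local_identity_coverage(query, target)
                if identity > max_id and coverage >= min_cov:
                    contaminated = True
                    break
            if contaminated:
                break
        if contaminated:
            removed += 1
        else:
            kept.append(entry)
    return kept, removed


# ---------------------------------------------------------------------------
# scoring and ROC


@dataclass
class RocCurve:
    """ROC sweep over all score thresholds plus the trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def score_genes(de_results: pd.DataFrame) -> pd.DataFrame:
    """Two-sided DE evidence score: 1 - nominal p (direction ignored)."""
    out = de_results.copy()
    out["score"] = 1.0 - out["p"]
    return out


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> RocCurve:
    """ROC curve and trapezoid AUC with simulated-DE features as positives."""
    y = np.asarray(truth, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("truth labels contain a single class")
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, auc)


# ---------------------------------------------------------------------------
# end-to-end mock experiments


@dataclass
class MockExperimentResult:
    auc: float
    roc: RocCurve
    de: pd.DataFrame
    scores: pd.Series  # per designed feature, 1 - nominal p (0 if undetected)
    truth: pd.Series
    design: MockDesign
    matrix: AbundanceMatrix
    run_stats: dict = field(default_factory=dict)


def _scores_for_design(
    de: pd.DataFrame, feature_of_gene: Mapping[str, str], design: MockDesign
) -> tuple[pd.Series, pd.Series]:
    """1 - p per designed gene; genes with no detected feature score 0."""
    p_by_feature = dict(zip(de["feature"], de["p"]))
    scores = {}
    for gene in design.labels:
        feature = feature_of_gene.get(gene, gene)
        scores[gene] = 1.0 - p_by_feature.get(feature, 1.0)
    return pd.Series(scores, name="score"), design.truth.loc[list(scores)]


def functional_mock_experiment(
    n_genes: int = 1000,
    n_per_group: int = 10,
    seed: int = 0,
    n_organisms: int = 5,
    mean_per_kb: float = 10.0,
    dispersion: float = 0.2,
    read_len: int = 76,
    workdir: str | Path | None = None,
) -> MockExperimentResult:
    """Functional mock benchmark: genes -> reads -> pipeline -> DE -> ROC.

    Draws ``n_genes`` genes from ``n_organisms`` synthetic organism pools,
    applies the 20%/20% 4-fold design, simulates counts and reads for two
    groups, runs QC / sorting / merging / ORF calling / clustering /
    catalog mapping / counting, tests the two groups, and evaluates the
    1 - p score against the simulated truth.
    """
    seeds = _child_seeds(seed, 6)
    pools = synthesize_source_genomes(
        n_organisms, max(2 * (n_genes // n_organisms), n_genes // n_organisms + 1), seed=seeds[0]
    )
    genes = build_mock(pools, genes_per_org=n_genes // n_organisms, seed=seeds[1])
    design = assign_de(
        genes,
        seed=seeds[2],
        n1=n_per_group,
        n2=n_per_group,
        mean_per_kb=mean_per_kb,
        dispersion=dispersion,
    )
    counts = simulate_counts(design, seed=seeds[3])
    quality = QualityModel.hiseq_like(read_len)
    catalog = CatalogIndex([CatalogEntry(g.id, g.seq) for g in genes])
    empty_index = KmerIndex()
    g1, g2 = design.samples

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        fastqs = simulate_reads(
            design, counts, quality, base / "reads", read_len=read_len, seed=seeds[4]
        )
        hits_by_sample = {}
        queries_by_sample = {}
        run_stats = {}
        for sample in g1 + g2:
            p1, p2 = fastqs[sample]
            kept, orphans = filter_pairs(read_fastq_pairs(p1, p2))
            collapsed = collapse_pairs(kept)
            buckets = sort_sample(collapsed, empty_index)
            mrna = buckets[RnaCategory.MRNA]
            merged, unmerged = merge_sample(mrna)
            hits, reps, fstats = quantify_functional(merged, unmerged, catalog)
            hits_by_sample[sample] = hits
            queries_by_sample[sample] = reps
            fstats.update(kept_pairs=len(kept), orphans=orphans, merged=len(merged))
            run_stats[sample] = fstats
    matrix = aggregate_counts(hits_by_sample, queries_by_sample)
    de = group_logratio_test(matrix, g1, g2)
    scores, truth = _scores_for_design(de, {}, design)
    roc = roc_auc(scores.to_numpy(), truth.to_numpy())
    return MockExperimentResult(
        roc.auc, roc, de, scores, truth, design, matrix, run_stats
    )


def taxonomic_mock_experiment(
    n_organisms: int = 200,
    n_per_group: int = 10,
    seed: int = 0,
    mean_per_kb: float = 10.0,
    dispersion: float = 0.2,
    read_len: int = 76,
    subsample: int = 100_000,
    workdir: str | Path | None = None,
) -> MockExperimentResult:
    """Taxonomic mock benchmark on a lineage-labeled synthetic community.

    The same 20%/20% 4-fold design is applied per organism; reads run
    through QC, merging, reservoir subsampling, OTU clustering, best-hit
    lineage assignment and rank tabulation; per-species DE scores are
    evaluated against the per-organism truth.
    """
    seeds = _child_seeds(seed, 6)
    refs = synthesize_16s_references(n_organisms, seed=seeds[0])
    reference = Reference16S(refs)
    organisms = [rec for rec, _ in refs]
    species_of = {rec.id: lin.name_at(len(lin.ranks) - 1) for rec, lin in refs}
    design = assign_de(
        organisms,
        seed=seeds[2],
        n1=n_per_group,
        n2=n_per_group,
        mean_per_kb=mean_per_kb,
        dispersion=dispersion,
    )
    counts = simulate_counts(design, seed=seeds[3])
    quality = QualityModel.hiseq_like(read_len)
    g1, g2 = design.samples

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        fastqs = simulate_reads(
            design, counts, quality, base / "reads", read_len=read_len, seed=seeds[4]
        )
        assignments = {}
        run_stats = {}
        sub_seeds = _child_seeds(seeds[5], len(g1 + g2))
        for i, sample in enumerate(g1 + g2):
            p1, p2 = fastqs[sample]
            kept, orphans = filter_pairs(read_fastq_pairs(p1, p2))
            merged, unmerged = merge_sample(kept)
            reads = list(merged) + [p.r1 for p in unmerged]
            sample_assign, unclassified = profile_sample(
                reads, reference, subsample=subsample, seed=sub_seeds[i]
            )
            assignments[sample] = sample_assign
            run_stats[sample] = {
                "kept_pairs": len(kept),
                "orphans": orphans,
                "merged": len(merged),
                "unclassified_weight": unclassified,
            }
    tables = build_rank_tables(assignments)
    species = tables["species"]
    de = group_logratio_test(species, g1, g2)
    scores, truth = _scores_for_design(de, species_of, design)
    roc = roc_auc(scores.to_numpy(), truth.to_numpy())
    return MockExperimentResult(
        roc.auc, roc, de, scores, truth, design, species, run_stats
    )
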