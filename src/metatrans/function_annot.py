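"""Functional quantification: ORF calling, clustering, catalog mapping, counting.

Putative-mRNA reads are reduced to gene fragments (maximal stop-free
stretches over all six frames), clustered greedily at >=95% identity over
>=90% of the shorter sequence with cluster sizes recorded in the
representative's header, mapped best-hit against an annotated gene catalog,
and aggregated into raw abundance matrices weighted by copies x cluster
size.  Gene counts roll up to orthologous groups and one-letter functional
categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

from ._align import (
    SeedIndex,
    local_identity_coverage,
    max_diagonal_overlap,
)
from .seqio import AbundanceMatrix, SeqRecord, read_fasta, revcomp

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
UNKNOWN_FEATURE = "unknown"


# ---------------------------------------------------------------------------
# gene fragment prediction


@dataclass
class GeneFragment:
    """A putative coding stretch on a read.

    ``start``/``end`` are 0-based half-open coordinates on the read (its
    original orientation); ``nt_seq`` is the coding-strand sequence, whose
    length is a multiple of 3.  Collapse tags are inherited from the read.
    """

    read_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset on the coding strand
    start: int
    end: int
    nt_seq: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def id(self) -> str:
        return f"{self.read_id}:{self.strand}{self.frame}:{self.start}-{self.end}"

    @property
    def seq(self) -> str:
        return self.nt_seq

    @property
    def copies(self) -> int:
        return self.tags.get("copies", 1)

    def __len__(self) -> int:
        return len(self.nt_seq)


def predict_fragments(read: SeqRecord, min_orf_len: int = 60) -> list[GeneFragment]:
    """All maximal stop-free stretches >= ``min_orf_len`` nt over 6 frames.

    Stretches are measured in whole codons using the standard genetic code
    stops (TAA, TAG, TGA).  Reads yielding no fragment are effectively
    discarded by the caller.
    """
    out: list[GeneFragment] = []
    n = len(read.seq)
    for strand in "+-":
        seq = read.seq if strand == "+" else revcomp(read.seq)
        for frame in range(3):
            ncod = (n - frame) // 3
            if ncod * 3 < min_orf_len:
                continue
            run_start = 0  # codon index where current stop-free run began
            for ci in range(ncod + 1):
                is_stop = ci < ncod and seq[frame + 3 * ci : frame + 3 * ci + 3] in STOP_CODONS
                if is_stop or ci == ncod:
                    run_len = ci - run_start
                    if run_len * 3 >= min_orf_len:
                        s = frame + 3 * run_start
                        e = frame + 3 * ci
                        if strand == "+":
                            start, end = s, e
                        else:
                            start, end = n - e, n - s
                        out.append(
                            GeneFragment(
                                read.id, strand, frame, start, end, seq[s:e], dict(read.tags)
                            )
                        )
                    run_start = ci + 1
    return out


def predict_sample_fragments(
    reads: Iterable[SeqRecord], min_orf_len: int = 60
) -> list[GeneFragment]:
    frags: list[GeneFragment] = []
    for read in reads:
        frags.extend(predict_fragments(read, min_orf_len))
    return frags


# ---------------------------------------------------------------------------
# greedy clustering


class _HasSeq(Protocol):
    id: str
    seq: str


@dataclass
class Cluster:
    """A greedy cluster: representative, members, and total read weight."""

    rep_id: str
    member_ids: list[str]
    weight: int
    rep: SeqRecord | None = None


def _member_copies(item) -> int:
    copies = getattr(item, "copies", None)
    if copies is not None:
        return int(copies)
    tags = getattr(item, "tags", None) or {}
    return int(tags.get("copies", 1))


def cluster_greedy(
    items: Sequence[_HasSeq],
    min_id: float = 95.0,
    min_cov: float = 0.90,
    csize_mode: str = "copies",
    seed_k: int = 8,
) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering.

    Items are sorted by length descending (stable, so ties keep input
    order); each item joins the first existing cluster whose representative
    aligns at identity >= ``min_id`` over >= ``min_cov`` of the shorter
    sequence, else founds a new cluster.  Cluster weight is the sum of
    member ``copies`` tags (``csize_mode='members'`` counts members
    instead) and is written into the representative's ``csize`` tag.

    A k-mer seed prefilter skips only representatives that provably cannot
    satisfy the alignment predicate, so results equal a brute-force scan
    over all representatives: any admissible alignment contains, by
    pigeonhole over its mismatch/gap budget, an exact run long enough to
    place a guaranteed number of shared k-mers on a single diagonal, and
    that diagonal must offer enough ungapped overlap.
    """
    if csize_mode not in ("copies", "members"):
        raise ValueError("csize_mode must be 'copies' or 'members'")
    order = sorted(range(len(items)), key=lambda i: -len(items[i].seq))
    clusters: list[Cluster] = []
    rep_index = SeedIndex([], k=seed_k)
    for i in order:
        item = items[i]
        qlen = len(item.seq)
        # alignment gaps can shift the seed diagonal by at most the identity
        # budget, so slacken the ungapped diagonal-overlap bound by that much
        budget = int((1.0 - min_id / 100.0) * qlen) + 2
        needed = min_cov * qlen - budget
        # pigeonhole: an admissible alignment has >= min_cov*qlen*min_id
        # matches broken by at most m_max mismatch/gap events (gap columns
        # can inflate the column count, hence the 1/min_id factor), so its
        # longest exact run carries this many k-mers on one diagonal
        frac_id = min_id / 100.0
        m_max = int((1.0 - frac_id) / frac_id * qlen) + 1
        run_min = int(min_cov * qlen * frac_id // (m_max + 1))
        needed_kmers = max(1, run_min - seed_k + 1)
        hits = rep_index.seed_hits(item.seq)
        joined = False
        for cidx in sorted(hits):
            diag_counts = hits[cidx]
            if max(diag_counts.values()) < needed_kmers:
                continue
            rep_seq = rep_index.sequences[cidx]
            if max_diagonal_overlap(qlen, len(rep_seq), diag_counts) < needed:
                continue
            if item.seq in rep_seq or item.seq == rep_seq:
                identity, coverage = 100.0, 1.0
            else:
                identity, coverage, _ = local_identity_coverage(item.seq, rep_seq)
            if identity >= min_id and coverage >= min_cov:
                cluster = clusters[cidx]
                cluster.member_ids.append(item.id)
                cluster.weight += _member_copies(item) if csize_mode == "copies" else 1
                joined = True
                break
        if not joined:
            rep_index.append(item.seq)
            clusters.append(
                Cluster(
                    rep_id=item.id,
                    member_ids=[item.id],
                    weight=_member_copies(item) if csize_mode == "copies" else 1,
                )
            )
    for cluster, rep_seq in zip(clusters, rep_index.sequences):
        # the cluster weight already includes the founder's own copies, so
        # the representative carries copies=1 and csize=weight; its total
        # weight (copies * csize) is then exactly the cluster weight.
        rep = SeqRecord(cluster.rep_id, rep_seq)
        rep.tags = {"copies": 1, "csize": cluster.weight}
        cluster.rep = rep
    return clusters


def cluster_representatives(clusters: Sequence[Cluster]) -> list[SeqRecord]:
    """Representative records with ``csize`` set to the cluster weight."""
    return [c.rep for c in clusters if c.rep is not None]


# ---------------------------------------------------------------------------
# catalog mapping


@dataclass
class CatalogEntry:
    """One gene of the reference catalog, with optional annotations."""

    gene_id: str
    seq: str
    og_id: str = ""
    ko_id: str = ""
    category: str = ""


@dataclass
class Hit:
    """Best-hit assignment of a query to a catalog entry."""

    query_id: str
    gene_id: str
    identity: float  # percent of aligned columns matching
    coverage: float  # aligned query length / query length
    aligned_len: int = 0


class CatalogIndex:
    """Seed-indexed gene catalog for best-hit mapping."""

    def __init__(self, entries: Sequence[CatalogEntry], k: int = 15):
        if not entries:
            raise ValueError("empty catalog")
        seen = set()
        for e in entries:
            if e.gene_id in seen:
                raise ValueError(f"duplicate gene_id {e.gene_id!r} in catalog")
            seen.add(e.gene_id)
        self.entries = list(entries)
        self.seed = SeedIndex([e.seq for e in entries], k=k)

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        annotations: pd.DataFrame | None = None,
        k: int = 15,
    ) -> "CatalogIndex":
        entries = []
        for rec in read_fasta(path):
            og = ko = cat = ""
            if annotations is not None and rec.id in annotations.index:
                row = annotations.loc[rec.id]
                og, ko, cat = row.get("og_id", ""), row.get("ko_id", ""), row.get("category", "")
            entries.append(CatalogEntry(rec.id, rec.seq, og, ko, cat))
        return cls(entries, k=k)


def map_best_hit(
    query: SeqRecord,
    catalog: CatalogIndex,
    min_id: float = 90.0,
    min_cov: float = 0.80,
    max_candidates: int = 5,
) -> Hit | None:
    """Deterministic best hit of a query against the catalog, or None.

    Both strands are searched.  Candidate targets sharing at least one
    seed are ranked by seed count; the top candidates are aligned and the
    best hit (highest identity, then longer alignment, then smallest
    gene_id) is returned if it meets ``min_id`` and ``min_cov``.
    """
    best: Hit | None = None
    best_key: tuple[float, int, str] | None = None
    for strand_seq in (query.seq, revcomp(query.seq)):
        counts = catalog.seed.seed_counts(strand_seq)
        if not counts:
            continue
        ranked = sorted(counts, key=lambda t: (-counts[t], t))[:max_candidates]
        # exact-substring fast path: a full-length perfect match (identity
        # 100, coverage 1) cannot be beaten by any gapped alignment, so no
        # candidate on this strand needs aligning
        exact = [t for t in ranked if strand_seq in catalog.entries[t].seq]
        if exact:
            entry = catalog.entries[min(exact, key=lambda t: catalog.entries[t].gene_id)]
            key = (-100.0, -len(strand_seq), entry.gene_id)
            if best_key is None or key < best_key:
                best_key = key
                best = Hit(query.id, entry.gene_id, 100.0, 1.0, len(strand_seq))
            continue
        for tidx in ranked:
            entry = catalog.entries[tidx]
            identity, coverage, aln_len = local_identity_coverage(strand_seq, entry.seq)
            if identity < min_id or coverage < min_cov:
                continue
            key = (-identity, -aln_len, entry.gene_id)
            if best_key is None or key < best_key:
                best_key = key
                best = Hit(query.id, entry.gene_id, identity, coverage, aln_len)
    return best


def map_sample(
    queries: Iterable[SeqRecord],
    catalog: CatalogIndex,
    min_id: float = 90.0,
    min_cov: float = 0.80,
) -> tuple[list[Hit], list[SeqRecord]]:
    """Best-hit mapping of a whole sample; returns (hits, unmapped queries)."""
    hits: list[Hit] = []
    unmapped: list[SeqRecord] = []
    for query in queries:
        hit = map_best_hit(query, catalog, min_id, min_cov)
        if hit is None:
            unmapped.append(query)
        else:
            hits.append(hit)
    return hits, unmapped


# ---------------------------------------------------------------------------
# counting and rollup


def aggregate_counts(
    hits_by_sample: Mapping[str, Sequence[Hit]],
    queries_by_sample: Mapping[str, Iterable[SeqRecord]],
) -> AbundanceMatrix:
    """Cluster-weighted raw gene counts per sample.

    Each query contributes ``copies x csize`` to its best-hit gene.
    Duplicate hits from the same query id within a sample are discarded
    with a warning (the best-hit contract allows at most one).
    """
    samples = list(hits_by_sample)
    weights: dict[str, dict[str, int]] = {
        s: {q.id: q.weight for q in queries_by_sample.get(s, ())} for s in samples
    }
    data: dict[str, dict[str, float]] = {}
    for sample in samples:
        seen: set[str] = set()
        for hit in hits_by_sample[sample]:
            if hit.query_id in seen:
                warnings.warn(
                    f"duplicate hit for query {hit.query_id!r} in sample {sample!r}; discarded"
                )
                continue
            seen.add(hit.query_id)
            w = weights[sample].get(hit.query_id, 1)
            row = data.setdefault(hit.gene_id, {})
            row[sample] = row.get(sample, 0) + w
    if not data:
        return AbundanceMatrix(pd.DataFrame(index=pd.Index([], name="feature"), columns=samples, dtype=float))
    return AbundanceMatrix.from_dict(data, samples=samples)


def rollup(
    matrix: AbundanceMatrix, annotations: pd.DataFrame
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Roll gene counts up to orthologous groups, then functional categories.

    Genes without an annotation (or absent from the map) accumulate under
    the ``unknown`` feature; likewise OGs without a category letter.
    Annotation rows referencing genes absent from the matrix are ignored
    with a warning.
    """
    absent = set(annotations.index) - set(matrix.features)
    if absent:
        warnings.warn(
            f"{len(absent)} annotation rows reference genes absent from the matrix"
        )
    og_of: dict[str, str] = {}
    cat_of_og: dict[str, str] = {UNKNOWN_FEATURE: UNKNOWN_FEATURE}
    for gene_id, row in annotations.iterrows():
        og = row.get("og_id", "") or UNKNOWN_FEATURE
        og_of[gene_id] = og
        cat = row.get("category", "") or UNKNOWN_FEATURE
        cat_of_og.setdefault(og, cat)
    og_groups = [og_of.get(g, UNKNOWN_FEATURE) for g in matrix.features]
    og_df = matrix.df.groupby(og_groups).sum()
    cat_groups = [cat_of_og.get(og, UNKNOWN_FEATURE) for og in og_df.index]
    cat_df = og_df.groupby(cat_groups).sum()
    return AbundanceMatrix(og_df), AbundanceMatrix(cat_df)


# ---------------------------------------------------------------------------
# per-sample functional chain


def quantify_functional(
    merged: Sequence[SeqRecord],
    unmerged_pairs: Sequence,
    catalog: CatalogIndex,
    min_orf_len: int = 60,
    cluster_min_id: float = 95.0,
    cluster_min_cov: float = 0.90,
    map_min_id: float = 90.0,
    map_min_cov: float = 0.80,
) -> tuple[list[Hit], list[SeqRecord], dict[str, int]]:
    """Merged reads + unmerged mates -> fragments -> clusters -> best hits.

    Returns the sample's hits, the cluster representatives used as mapping
    queries (tag source for counting), and stage counts for the run log.
    """
    reads: list[SeqRecord] = list(merged)
    for pair in unmerged_pairs:
        reads.append(pair.r1)
        reads.append(pair.r2)
    all_frags = predict_sample_fragments(reads, min_orf_len)
    # one putative gene per short read: keep the longest fragment (first on
    # ties), so a read is counted at most once downstream
    best_by_read: dict[str, GeneFragment] = {}
    for frag in all_frags:
        cur = best_by_read.get(frag.read_id)
        if cur is None or len(frag) > len(cur):
            best_by_read[frag.read_id] = frag
    frags = list(best_by_read.values())
    clusters = cluster_greedy(frags, cluster_min_id, cluster_min_cov)
    reps = []
    for cluster in clusters:
        rep = cluster.rep
        assert rep is not None
        reps.append(rep)
    hits, unmapped = map_sample(reps, catalog, map_min_id, map_min_cov)
    stats = {
        "reads": len(reads),
        "fragments": len(frags),
        "clusters": len(clusters),
        "mapped": len(hits),
        "unmapped": len(unmapped),
    }
    return hits, reps, stats
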