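"""16S taxonomic profiling.

Structural-RNA reads are merged, uniformly subsampled with a single-pass
reservoir (default 100,000 reads), pre-clustered at the conventional 97%
OTU radius, assigned a Greengenes-style 7-rank lineage by best-hit mapping
against a 16S reference, and tabulated into per-rank raw-count tables.
Tables drop per-sample singletons (count == 1 in a sample is set to 0 to
avoid false-positive assignments) and are sorted by mean abundance
descending.  Utilities for relative-abundance filtering and rarefaction to
a fixed depth (default 1,952 reads per sample) round out the module.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TypeVar

import numpy as np
import pandas as pd

from .function_annot import CatalogEntry, CatalogIndex, cluster_greedy, map_best_hit
from .seqio import AbundanceMatrix, SeqRecord, read_fasta

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

T = TypeVar("T")


@dataclass(frozen=True)
class Lineage:
    """Seven Greengenes-prefixed rank strings; an empty name means unknown."""

    ranks: tuple[str, str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"lineage needs {len(RANKS)} ranks, got {len(self.ranks)}")
        for value, prefix in zip(self.ranks, RANK_PREFIXES):
            if value and not value.startswith(prefix):
                raise ValueError(f"rank {value!r} lacks prefix {prefix!r}")

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        parts = [p.strip() for p in text.split(";")]
        if len(parts) != len(RANKS):
            raise ValueError(
                f"lineage {text!r} has {len(parts)} fields, expected {len(RANKS)}"
            )
        return cls(tuple(parts))  # type: ignore[arg-type]

    def name_at(self, rank: int) -> str:
        """Feature name at a rank index: the lineage truncated to that rank,
        with unknown trailing ranks grouped under the deepest known prefix."""
        prefix = list(self.ranks[: rank + 1])
        while prefix and (not prefix[-1] or len(prefix[-1]) <= 3):
            prefix.pop()
        if not prefix:
            return "unclassified"
        return "; ".join(prefix)

    def __str__(self) -> str:
        return "; ".join(self.ranks)


def read_16s_reference(path: str | Path) -> list[tuple[SeqRecord, Lineage]]:
    """Load a 16S FASTA whose descriptions carry 7-rank lineages.

    Header dialect: ``>id<TAB>k__X; p__X; c__X; o__X; f__X; g__X; s__X``.
    """
    out: list[tuple[SeqRecord, Lineage]] = []
    for rec in read_fasta(path, keep_description=True):
        description = getattr(rec, "description", "")
        if not description:
            raise ValueError(f"16S record {rec.id!r} lacks a lineage description")
        try:
            lineage = Lineage.parse(description)
        except ValueError as exc:
            raise ValueError(f"16S record {rec.id!r}: {exc}") from exc
        out.append((rec, lineage))
    return out


class Reference16S:
    """Seed-indexed 16S reference with per-entry lineages."""

    def __init__(self, records: Sequence[tuple[SeqRecord, Lineage]], k: int = 15):
        if not records:
            raise ValueError("empty 16S reference")
        self.lineages = [lin for _, lin in records]
        self.catalog = CatalogIndex(
            [CatalogEntry(rec.id, rec.seq) for rec, _ in records], k=k
        )
        self._by_id = {rec.id: lin for rec, lin in records}

    @classmethod
    def from_fasta(cls, path: str | Path, k: int = 15) -> "Reference16S":
        return cls(read_16s_reference(path), k=k)

    def lineage_of(self, ref_id: str) -> Lineage:
        return self._by_id[ref_id]


# ---------------------------------------------------------------------------
# subsampling


def reservoir_sample(
    items: Iterable[T], capacity: int = 100_000, seed: int = 0
) -> list[T]:
    """Single-pass uniform sample of ``capacity`` items (Algorithm R).

    Every element of the stream is retained with equal probability
    capacity/seen; deterministic for a given seed.  Order of the returned
    list is an implementation detail of the reservoir.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    rng = random.Random(seed)
    reservoir: list[T] = []
    for i, item in enumerate(items):
        if i < capacity:
            reservoir.append(item)
        else:
            j = rng.randrange(i + 1)
            if j < capacity:
                reservoir[j] = item
    return reservoir


# ---------------------------------------------------------------------------
# lineage assignment


def assign_lineage(
    query: SeqRecord,
    reference: Reference16S,
    min_id: float = 90.0,
    min_cov: float = 0.80,
) -> Lineage | None:
    """Best-hit lineage of a query, or None when unclassified."""
    hit = map_best_hit(query, reference.catalog, min_id, min_cov)
    if hit is None:
        return None
    return reference.lineage_of(hit.gene_id)


def profile_sample(
    reads: Sequence[SeqRecord],
    reference: Reference16S,
    subsample: int = 100_000,
    seed: int = 0,
    cluster_min_id: float = 97.0,
    cluster_min_cov: float = 0.90,
    map_min_id: float = 90.0,
    map_min_cov: float = 0.80,
) -> tuple[list[tuple[Lineage, int]], int]:
    """Subsample, cluster at the OTU radius, and assign lineages.

    Returns (list of (lineage, weight) assignments, unclassified weight);
    weight is copies x cluster size of each classified representative.
    """
    sampled = reservoir_sample(reads, subsample, seed)
    clusters = cluster_greedy(sampled, cluster_min_id, cluster_min_cov)
    assignments: list[tuple[Lineage, int]] = []
    unclassified = 0
    for cluster in clusters:
        rep = cluster.rep
        assert rep is not None
        lineage = assign_lineage(rep, reference, map_min_id, map_min_cov)
        if lineage is None:
            unclassified += rep.weight
        else:
            assignments.append((lineage, rep.weight))
    return assignments, unclassified


# ---------------------------------------------------------------------------
# rank tables


def build_rank_tables(
    assignments: Mapping[str, Sequence[tuple[Lineage, int]]],
    remove_singletons: bool = True,
) -> dict[str, AbundanceMatrix]:
    """Per-rank raw-count tables from per-sample lineage assignments.

    At rank r the feature is the lineage truncated to r (unknown trailing
    ranks grouped under the deepest known prefix).  After construction,
    cells equal to 1 are zeroed (per-sample singleton removal) and rows are
    sorted by row mean descending.
    """
    samples = list(assignments)
    tables: dict[str, AbundanceMatrix] = {}
    for rank_idx, rank_name in enumerate(RANKS):
        data: dict[str, dict[str, float]] = {}
        for sample in samples:
            for lineage, weight in assignments[sample]:
                feature = lineage.name_at(rank_idx)
                row = data.setdefault(feature, {})
                row[sample] = row.get(sample, 0) + weight
        if data:
            df = pd.DataFrame.from_dict(data, orient="index").reindex(columns=samples).fillna(0.0)
        else:
            df = pd.DataFrame(index=pd.Index([], name="feature"), columns=samples, dtype=float)
        if remove_singletons:
            df = df.mask(df == 1, 0.0)
        df = df.loc[df.mean(axis=1).sort_values(ascending=False, kind="stable").index]
        tables[rank_name] = AbundanceMatrix(df)
    return tables


def filter_taxa(matrix: AbundanceMatrix, min_frac: float) -> AbundanceMatrix:
    """Keep features reaching ``min_frac`` of the reads in >= 1 sample.

    Sample totals of zero are excluded from the maximum with a warning.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    df = matrix.df
    totals = df.sum(axis=0)
    nonzero = totals[totals > 0].index
    if len(nonzero) < len(totals):
        warnings.warn("samples with zero total excluded from taxon filtering")
    if len(nonzero) == 0 or df.empty:
        return AbundanceMatrix(df.iloc[0:0])
    frac = df[nonzero] / totals[nonzero]
    keep = frac.max(axis=1) >= min_frac
    return AbundanceMatrix(df.loc[keep])


def rarefy(matrix: AbundanceMatrix, depth: int = 1952, seed: int = 0) -> AbundanceMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Multivariate hypergeometric draw per sample; samples with fewer than
    ``depth`` reads are dropped with a warning.  Deterministic given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    df = matrix.df
    kept_cols = []
    columns = {}
    for sample in df.columns:
        counts = df[sample].to_numpy()
        total = counts.sum()
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {int(total)} < {depth} reads; dropped from rarefaction"
            )
            continue
        if total == depth:
            columns[sample] = counts.astype(float)
        else:
            drawn = rng.multivariate_hypergeometric(
                np.asarray(np.rint(counts), dtype=np.int64), depth
            )
            columns[sample] = drawn.astype(float)
        kept_cols.append(sample)
    out = pd.DataFrame(columns, index=df.index).reindex(columns=kept_cols)
    return AbundanceMatrix(out)
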