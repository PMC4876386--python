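"""Sorting reads into rRNA/tRNA categories versus potential mRNA.

Reads are screened against user-supplied reference sets for the four
structural-RNA categories (16S/18S small subunit, 23S/28S large subunit,
5S, tRNA) using canonical k-mer containment: a read is assigned the
category whose references share the largest fraction of its k-mers,
provided that fraction reaches ``min_frac``; everything else is kept as
potential mRNA.  Pairs stay linked: one structural-RNA mate condemns the
whole pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .seqio import ReadPair, SeqRecord, read_fasta, revcomp


class RnaCategory(str, Enum):
    SSU = "SSU"        # 16S/18S rRNA
    LSU = "LSU"        # 23S/28S rRNA
    FIVE_S = "FIVE_S"  # 5S (and any user-supplied 5.8S) rRNA
    TRNA = "TRNA"
    MRNA = "MRNA"      # unclassified leftover = potential mRNA


#: Fixed tie-break priority for classification (MRNA is the fallback).
CATEGORY_PRIORITY: tuple[RnaCategory, ...] = (
    RnaCategory.SSU,
    RnaCategory.LSU,
    RnaCategory.FIVE_S,
    RnaCategory.TRNA,
)

_VALID = frozenset("ACGT")


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (lexicographic min of strand pair) k-mers; k-mers containing
    characters outside ACGT are skipped."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if not _VALID.issuperset(kmer):
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


@dataclass
class KmerIndex:
    """Per-category sets of canonical reference k-mers."""

    k: int = 15
    categories: dict[RnaCategory, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")


def build_index(
    refs: Mapping[RnaCategory, str | Path | Iterable[SeqRecord]], k: int = 15
) -> KmerIndex:
    """Index reference FASTA files (or record iterables) per category.

    An empty reference set for a listed category is a configuration error.
    """
    index = KmerIndex(k=k)
    for category, source in refs.items():
        category = RnaCategory(category)
        records = (
            list(read_fasta(source))
            if isinstance(source, (str, Path))
            else list(source)
        )
        if not records:
            raise ValueError(f"empty reference set for category {category.value}")
        kmers: set[str] = set()
        for rec in records:
            kmers |= canonical_kmers(rec.seq, k)
        index.categories[category] = kmers
    return index


def classify_read(
    read: SeqRecord, index: KmerIndex, min_frac: float = 0.25
) -> RnaCategory:
    """Assign one read to a structural-RNA category or potential mRNA.

    The score per category is the fraction of the read's canonical k-mers
    found in that category's reference set; the argmax wins if it reaches
    ``min_frac`` (ties broken by the fixed priority order).  Reads shorter
    than k cannot be scored and fall through to mRNA with a warning.
    """
    if not any(index.categories.values()):
        return RnaCategory.MRNA
    if len(read.seq) < index.k:
        warnings.warn(
            f"read {read.id!r} shorter than k={index.k}; classified as MRNA"
        )
        return RnaCategory.MRNA
    kmers = canonical_kmers(read.seq, index.k)
    if not kmers:
        return RnaCategory.MRNA
    best = RnaCategory.MRNA
    best_frac = 0.0
    for category in CATEGORY_PRIORITY:
        ref = index.categories.get(category)
        if not ref:
            continue
        frac = len(kmers & ref) / len(kmers)
        if frac > best_frac:
            best, best_frac = category, frac
    if best_frac >= min_frac and best is not RnaCategory.MRNA:
        return best
    return RnaCategory.MRNA


def classify_pair(
    pair: ReadPair, index: KmerIndex, min_frac: float = 0.25
) -> RnaCategory:
    """Pair-level category: the highest-priority structural category of
    either mate, else mRNA."""
    c1 = classify_read(pair.r1, index, min_frac)
    c2 = classify_read(pair.r2, index, min_frac)
    for category in CATEGORY_PRIORITY:
        if c1 is category or c2 is category:
            return category
    return RnaCategory.MRNA


def sort_sample(
    pairs: Iterable[ReadPair], index: KmerIndex, min_frac: float = 0.25
) -> dict[RnaCategory, list[ReadPair]]:
    """Partition pairs into one bucket per category (every pair in exactly one)."""
    buckets: dict[RnaCategory, list[ReadPair]] = {c: [] for c in RnaCategory}
    for pair in pairs:
        buckets[classify_pair(pair, index, min_frac)].append(pair)
    return buckets
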