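"""Read quality control: trimming, pair filtering, collapsing, overlap merging.

The QC stage trims terminal N runs and low-quality 3' tails, drops short
reads, discards orphaned mates, and collapses identical reads into one
representative carrying a ``copies`` tag.  Putative-mRNA mates are later
merged into a single longer read where their 3' ends overlap (minimum 8 bp
overlap, at most 10% mismatches by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .seqio import ReadPair, SeqRecord, revcomp, strip_mate_suffix


@dataclass(frozen=True)
class TrimPolicy:
    """Quality trimming thresholds.

    min_phred: bases on the 3' tail below this Phred score are trimmed.
    min_len:   reads shorter than this after trimming are rejected.
    trim_cluster_n: remove leading/trailing maximal runs of N.
    adapter:   optional 3' adapter sequence, clipped when a prefix of it
               (>= 8 bp) matches the read 3' end; off by default.
    """

    min_phred: int = 10
    min_len: int = 30
    trim_cluster_n: bool = True
    adapter: str | None = None

    def __post_init__(self) -> None:
        if self.min_phred < 0:
            raise ValueError("min_phred must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class MergePolicy:
    """Paired-end overlap merge thresholds (Fastq-Join-style)."""

    min_overlap: int = 8
    max_diff: float = 0.10

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_diff <= 1.0:
            raise ValueError("max_diff must be in [0, 1]")


def _clip_adapter(seq: str, qual: list[int], adapter: str, min_match: int = 8) -> tuple[str, list[int]]:
    for i in range(len(seq) - min_match + 1):
        tail = seq[i:]
        if adapter.startswith(tail[: len(adapter)]) and len(tail) >= min_match:
            return seq[:i], qual[:i]
    return seq, qual


def trim_read(read: SeqRecord, policy: TrimPolicy = TrimPolicy()) -> SeqRecord | None:
    """Trim one read; returns None when it fails the length filter.

    Order of operations: clip terminal N runs, clip the low-quality 3' tail
    (the maximal suffix whose bases are all below ``min_phred``), optionally
    clip a 3' adapter, then apply the minimum-length filter.
    """
    if read.qual is None:
        raise ValueError(f"read {read.id!r} has no qualities; cannot quality-trim")
    seq, qual = read.seq, list(read.qual)
    if policy.trim_cluster_n:
        start = 0
        while start < len(seq) and seq[start] == "N":
            start += 1
        end = len(seq)
        while end > start and seq[end - 1] == "N":
            end -= 1
        seq, qual = seq[start:end], qual[start:end]
    cut = len(seq)
    while cut > 0 and qual[cut - 1] < policy.min_phred:
        cut -= 1
    seq, qual = seq[:cut], qual[:cut]
    if policy.adapter:
        seq, qual = _clip_adapter(seq, qual, policy.adapter.upper())
    if len(seq) < policy.min_len:
        return None
    return SeqRecord(read.id, seq, qual, dict(read.tags))


def filter_pairs(
    pairs: Iterable[ReadPair], policy: TrimPolicy = TrimPolicy()
) -> tuple[list[ReadPair], int]:
    """Trim both mates of each pair; keep only pairs where both survive.

    Returns the surviving pairs (input order preserved) and the number of
    orphans, i.e. pairs where exactly one mate passed and was discarded to
    keep the files synchronized.
    """
    kept: list[ReadPair] = []
    orphans = 0
    for pair in pairs:
        t1 = trim_read(pair.r1, policy)
        t2 = trim_read(pair.r2, policy)
        if t1 is not None and t2 is not None:
            kept.append(ReadPair(t1, t2))
        elif t1 is not None or t2 is not None:
            orphans += 1
    return kept, orphans


def collapse_identical(reads: Iterable[SeqRecord]) -> list[SeqRecord]:
    """Collapse reads with identical sequence strings into one record.

    The representative keeps the first-seen id, sums the member ``copies``
    tags, and takes the per-position maximum quality over members.  Output
    is sorted by copies descending, then id.
    """
    buckets: dict[str, SeqRecord] = {}
    for read in reads:
        rep = buckets.get(read.seq)
        if rep is None:
            rec = SeqRecord(read.id, read.seq, list(read.qual) if read.qual else None, dict(read.tags))
            buckets[read.seq] = rec
        else:
            rep.copies = rep.copies + read.copies
            if rep.qual is not None and read.qual is not None:
                rep.qual = [max(a, b) for a, b in zip(rep.qual, read.qual)]
    out = list(buckets.values())
    out.sort(key=lambda r: (-r.copies, r.id))
    return out


def collapse_pairs(pairs: Iterable[ReadPair]) -> list[ReadPair]:
    """Collapse pairs whose (mate1, mate2) sequences are both identical.

    Pair-level analogue of :func:`collapse_identical` that preserves the
    mate link; both mates of the representative carry the summed copies.
    """
    buckets: dict[tuple[str, str], ReadPair] = {}
    for pair in pairs:
        key = (pair.r1.seq, pair.r2.seq)
        rep = buckets.get(key)
        if rep is None:
            buckets[key] = ReadPair(
                SeqRecord(pair.r1.id, pair.r1.seq, list(pair.r1.qual) if pair.r1.qual else None, dict(pair.r1.tags)),
                SeqRecord(pair.r2.id, pair.r2.seq, list(pair.r2.qual) if pair.r2.qual else None, dict(pair.r2.tags)),
            )
        else:
            copies = rep.r1.copies + pair.r1.copies
            rep.r1.copies = copies
            rep.r2.copies = copies
            for mate_rep, mate_new in ((rep.r1, pair.r1), (rep.r2, pair.r2)):
                if mate_rep.qual is not None and mate_new.qual is not None:
                    mate_rep.qual = [max(a, b) for a, b in zip(mate_rep.qual, mate_new.qual)]
    out = list(buckets.values())
    out.sort(key=lambda p: (-p.r1.copies, p.r1.id))
    return out


# ---------------------------------------------------------------------------
# overlap merging


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_counts_all_offsets(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Number of matching positions for every offset of a2 against a1.

    Offset ``o`` places ``a2[j]`` against ``a1[o + j]``; the returned array
    is indexed by ``o + (len(a2) - 1)`` and is computed as a sum of one-hot
    cross-correlations per base letter.  N aligned to N counts as a match,
    matching plain character equality.
    """
    n1, n2 = len(a1), len(a2)
    total = np.zeros(n1 + n2 - 1)
    for base in (65, 67, 71, 84, 78):  # A C G T N
        u = (a1 == base).astype(np.float64)
        v = (a2 == base).astype(np.float64)
        if u.any() and v.any():
            total += np.correlate(u, v, mode="full")
    return np.rint(total).astype(np.int64)


def find_best_overlap(
    s1: str, s2_rc: str, policy: MergePolicy = MergePolicy()
) -> tuple[int, int, int] | None:
    """Best overlap placement of ``s2_rc`` against ``s1``.

    Considers every offset (including negative offsets where the
    reverse-complemented mate starts before mate 1, i.e. read-through).
    A candidate overlap must span >= ``min_overlap`` positions with a
    mismatch fraction <= ``max_diff``.  The longest candidate wins; ties
    prefer fewer mismatches, then the smaller offset.  Returns
    ``(offset, overlap_len, mismatches)`` or None.
    """
    n1, n2 = len(s1), len(s2_rc)
    if min(n1, n2) < policy.min_overlap:
        return None
    a1, a2 = _encode(s1), _encode(s2_rc)
    matches = _match_counts_all_offsets(a1, a2)
    best: tuple[int, int, int] | None = None  # (-L, mism, offset)
    for offset in range(-(n2 - policy.min_overlap), n1 - policy.min_overlap + 1):
        length = min(n1, offset + n2) - max(0, offset)
        if length < policy.min_overlap:
            continue
        mism = length - int(matches[offset + n2 - 1])
        if mism > policy.max_diff * length:
            continue
        key = (-length, mism, offset)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], -best[0], best[1]


def merge_pair(pair: ReadPair, policy: MergePolicy = MergePolicy()) -> SeqRecord | None:
    """Merge two mates into one longer read, or return None when impossible.

    Mate 2 is reverse-complemented before the overlap search.  In the
    overlapped region the base with the higher quality is emitted (mate 1
    wins ties) together with the maximum of the two qualities.
    """
    s1 = pair.r1.seq
    s2 = revcomp(pair.r2.seq)
    q1 = pair.r1.qual if pair.r1.qual is not None else [0] * len(s1)
    q2 = list(reversed(pair.r2.qual)) if pair.r2.qual is not None else [0] * len(s2)
    hit = find_best_overlap(s1, s2, policy)
    if hit is None:
        return None
    offset, _, _ = hit
    lo = min(0, offset)
    hi = max(len(s1), offset + len(s2))
    seq_chars: list[str] = []
    quals: list[int] = []
    for pos in range(lo, hi):
        in1 = 0 <= pos < len(s1)
        j = pos - offset
        in2 = 0 <= j < len(s2)
        if in1 and in2:
            if q2[j] > q1[pos]:
                seq_chars.append(s2[j])
            else:
                seq_chars.append(s1[pos])
            quals.append(max(q1[pos], q2[j]))
        elif in1:
            seq_chars.append(s1[pos])
            quals.append(q1[pos])
        else:
            seq_chars.append(s2[j])
            quals.append(q2[j])
    has_qual = pair.r1.qual is not None or pair.r2.qual is not None
    return SeqRecord(
        strip_mate_suffix(pair.r1.id),
        "".join(seq_chars),
        quals if has_qual else None,
        dict(pair.r1.tags),
    )


def merge_sample(
    pairs: Iterable[ReadPair], policy: MergePolicy = MergePolicy()
) -> tuple[list[SeqRecord], list[ReadPair]]:
    """Merge every pair that overlaps; return (merged reads, unmerged pairs)."""
    merged: list[SeqRecord] = []
    unmerged: list[ReadPair] = []
    for pair in pairs:
        rec = merge_pair(pair, policy)
        if rec is None:
            unmerged.append(pair)
        else:
            merged.append(rec)
    return merged, unmerged
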