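"""Shared pairwise-alignment and k-mer seeding helpers.

Local (Smith-Waterman-style) alignment is provided by Bio.Align with
BLAST-like nucleotide scoring (match +2, mismatch -3, gap open -5, gap
extend -2).  From the best local alignment we report

* identity: matching columns / aligned columns (gap columns included), as
  a percentage, and
* coverage: the aligned span on the query divided by the query length.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from Bio import Align

from .seqio import revcomp

MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_ALIGNER = make_aligner()


def local_identity_coverage(query: str, target: str) -> tuple[float, float, int]:
    """Identity (%), query coverage (0..1) and aligned length of the best
    local alignment of ``query`` against ``target``.

    Returns ``(0.0, 0.0, 0)`` when no positive-scoring alignment exists.
    """
    if not query or not target:
        return 0.0, 0.0, 0
    alignments = _ALIGNER.align(query, target)
    if alignments.score <= 0:
        return 0.0, 0.0, 0
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0
    qry_blocks, tgt_blocks = aln.aligned
    matches = 0
    aligned_cols = 0
    prev_t = prev_q = None
    for (q0, q1), (t0, t1) in zip(qry_blocks, tgt_blocks):
        if prev_t is not None:
            aligned_cols += (t0 - prev_t) + (q0 - prev_q)  # internal gap columns
        for a, b in zip(target[t0:t1], query[q0:q1]):
            if a == b:
                matches += 1
        aligned_cols += t1 - t0
        prev_t, prev_q = t1, q1
    if aligned_cols == 0:
        return 0.0, 0.0, 0
    q_start = qry_blocks[0][0]
    q_end = qry_blocks[-1][1]
    identity = 100.0 * matches / aligned_cols
    coverage = (q_end - q_start) / len(query)
    return identity, coverage, aligned_cols


def kmer_positions(seq: str, k: int) -> list[tuple[int, str]]:
    """(position, k-mer) pairs, skipping k-mers containing non-ACGT."""
    valid = frozenset("ACGT")
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if valid.issuperset(kmer):
            out.append((i, kmer))
    return out


class SeedIndex:
    """Inverted k-mer index over a fixed set of target sequences.

    Maps k-mer -> list of (target index, position); used both for
    candidate retrieval (seed counting) and for diagonal-overlap bounds.
    """

    def __init__(self, sequences: Sequence[str], k: int = 15):
        if k < 4:
            raise ValueError("seed k must be >= 4")
        self.k = k
        self.sequences = list(sequences)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(self.sequences):
            self._add(idx, seq)

    def _add(self, idx: int, seq: str) -> None:
        for pos, kmer in kmer_positions(seq, self.k):
            self.index.setdefault(kmer, []).append((idx, pos))

    def append(self, seq: str) -> int:
        """Add one more target (used by incremental greedy clustering)."""
        idx = len(self.sequences)
        self.sequences.append(seq)
        self._add(idx, seq)
        return idx

    def seed_hits(self, query: str) -> dict[int, dict[int, int]]:
        """Per-target seed diagonals with multiplicity.

        Maps target index -> {diagonal: number of shared k-mers on it},
        where a diagonal is target_pos - query_pos.
        """
        hits: dict[int, dict[int, int]] = {}
        for qpos, kmer in kmer_positions(query, self.k):
            for tidx, tpos in self.index.get(kmer, ()):
                diags = hits.setdefault(tidx, {})
                d = tpos - qpos
                diags[d] = diags.get(d, 0) + 1
        return hits

    def seed_counts(self, query: str) -> dict[int, int]:
        """Number of shared seeds per target (for candidate ranking)."""
        counts: dict[int, int] = {}
        for _, kmer in kmer_positions(query, self.k):
            for tidx, _ in self.index.get(kmer, ()):
                counts[tidx] = counts.get(tidx, 0) + 1
        return counts


def max_diagonal_overlap(qlen: int, tlen: int, diagonals: Iterable[int]) -> int:
    """Largest possible ungapped overlap between query and target over the
    given seed diagonals (d = target_pos - query_pos)."""
    best = 0
    for d in diagonals:
        overlap = min(qlen, tlen - d) - max(0, -d)
        if overlap > best:
            best = overlap
    return best


def best_strand_query(query: str) -> tuple[str, str]:
    """Both search strands of a query: (forward, reverse complement)."""
    return query, revcomp(query)
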