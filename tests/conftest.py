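"""Shared fixtures: small synthetic records and on-disk FASTQ/FASTA helpers."""

from __future__ import annotations

import numpy as np
import pytest

from metatrans.seqio import ReadPair, SeqRecord, write_fasta, write_fastq


@pytest.fixture
def rng():
    return np.random.default_rng(20160523)


def make_read(ident: str, seq: str, qual=40, tags=None) -> SeqRecord:
    if isinstance(qual, int):
        qual = [qual] * len(seq)
    return SeqRecord(ident, seq, qual, dict(tags or {}))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=n))


def mutate_at(seq: str, positions) -> str:
    order = "ACGT"
    out = list(seq)
    for pos in positions:
        out[pos] = order[(order.index(out[pos]) + 1) % 4]
    return "".join(out)


@pytest.fixture
def fastq_pair_files(tmp_path):
    """Factory writing two synchronized FASTQ files; returns their paths."""

    def _write(pairs: list[ReadPair]):
        p1 = tmp_path / "reads_1.fastq"
        p2 = tmp_path / "reads_2.fastq"
        write_fastq((p.r1 for p in pairs), p1)
        write_fastq((p.r2 for p in pairs), p2)
        return p1, p2

    return _write


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="ref.fasta"):
        path = tmp_path / name
        write_fasta(records, path)
        return path

    return _write
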