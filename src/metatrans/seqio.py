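"""Sequence and table I/O for the pipeline.

Reads and writes FASTQ (CASAVA 1.8, Phred+33), FASTA and TSV abundance
matrices, and implements the pipeline's header-tag convention: collapse
copy counts and cluster sizes travel with a sequence as ``|copies=N`` and
``|csize=M`` suffixes appended to the id token, e.g. ``read7|copies=3|csize=5``.
Tags equal to 1 are omitted on output, so untouched headers round-trip
bit-exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
#: Highest accepted Phred score (HiSeq range); larger encodings are rejected.
MAX_PHRED = 41

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastqParseError(ValueError):
    """Malformed FASTQ/FASTA record; the message names the record index."""


class TagFormatError(ValueError):
    """Invalid ``|key=value`` header tag."""


class PairingError(ValueError):
    """Mate files out of sync: ids differ at the same record position."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# header tags


def parse_tags(header: str) -> tuple[str, dict[str, int]]:
    """Split an id token of the form ``id|copies=N|csize=M``.

    Returns the bare id and a tag dict in which ``copies`` and ``csize``
    are always present, defaulting to 1 when absent from the header.
    """
    parts = header.split("|")
    ident = parts[0]
    tags: dict[str, int] = {"copies": 1, "csize": 1}
    for part in parts[1:]:
        key, sep, raw = part.partition("=")
        if not sep or not key:
            raise TagFormatError(f"malformed tag {part!r} in header {header!r}")
        try:
            value = int(raw)
        except ValueError:
            raise TagFormatError(
                f"non-integer value {raw!r} for tag {key!r} in header {header!r}"
            ) from None
        if value < 1:
            raise TagFormatError(
                f"non-positive value {value} for tag {key!r} in header {header!r}"
            )
        tags[key] = value
    return ident, tags


def format_tags(ident: str, tags: dict[str, int] | None) -> str:
    """Inverse of :func:`parse_tags`; tags with value 1 are omitted."""
    if not tags:
        return ident
    out = [ident]
    for key in ("copies", "csize"):
        if tags.get(key, 1) != 1:
            out.append(f"{key}={tags[key]}")
    for key, value in tags.items():
        if key not in ("copies", "csize") and value != 1:
            out.append(f"{key}={value}")
    return "|".join(out)


# ---------------------------------------------------------------------------
# records


@dataclass
class SeqRecord:
    """One read or reference sequence.

    ``qual`` is a list of Phred integers (0..41) of the same length as
    ``seq``, or None for FASTA input.  ``tags`` carries the collapse copy
    count and cluster size; absent means 1.
    """

    id: str
    seq: str
    qual: list[int] | None = None
    tags: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    @property
    def copies(self) -> int:
        return self.tags.get("copies", 1)

    @copies.setter
    def copies(self, value: int) -> None:
        self.tags["copies"] = int(value)

    @property
    def csize(self) -> int:
        return self.tags.get("csize", 1)

    @csize.setter
    def csize(self, value: int) -> None:
        self.tags["csize"] = int(value)

    @property
    def weight(self) -> int:
        """Total reads this record stands for: copies x cluster size."""
        return self.copies * self.csize

    @property
    def header(self) -> str:
        return format_tags(self.id, self.tags)

    def __len__(self) -> int:
        return len(self.seq)


def strip_mate_suffix(ident: str) -> str:
    """Drop trailing ``/1`` / ``/2`` mate markers from a read id.

    CASAVA 1.8 mate info lives in the second whitespace-separated token and
    is already dropped when the id token is taken, so only the classic
    suffix form needs stripping.
    """
    if ident.endswith(("/1", "/2")):
        return ident[:-2]
    return ident


@dataclass
class ReadPair:
    """Two mates of one sequenced fragment; ids agree after suffix stripping."""

    r1: SeqRecord
    r2: SeqRecord

    def __post_init__(self) -> None:
        if strip_mate_suffix(self.r1.id) != strip_mate_suffix(self.r2.id):
            raise PairingError(
                f"mate ids differ: {self.r1.id!r} vs {self.r2.id!r}"
            )

    @property
    def id(self) -> str:
        return strip_mate_suffix(self.r1.id)


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def _open(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream Phred+33 FASTQ records in file order.

    Malformed records raise :class:`FastqParseError` naming the (0-based)
    record index; quality characters above Phred 41 are rejected.
    """
    with _open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual_str = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            if len(seq) != len(qual_str):
                raise FastqParseError(
                    f"record {index}: sequence/quality length mismatch"
                )
            qual = [ord(c) - PHRED_OFFSET for c in qual_str]
            for q in qual:
                if q < 0 or q > MAX_PHRED:
                    raise FastqParseError(
                        f"record {index}: Phred score {q} outside 0..{MAX_PHRED}"
                    )
            ident, tags = parse_tags(title.split()[0])
            yield SeqRecord(ident, seq.upper(), qual, tags)
            index += 1


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open(path, "wt") as handle:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual_str = "".join(chr(q + PHRED_OFFSET) for q in rec.qual)
            handle.write(f"@{rec.header}\n{rec.seq}\n+\n{qual_str}\n")
            n += 1
    return n


def read_fasta(path: str | Path, keep_description: bool = False) -> Iterator[SeqRecord]:
    """Stream FASTA records; set ``keep_description`` to retain the full title.

    With ``keep_description`` the record id is the first token and the rest
    of the title line is stored under ``rec.description`` (used for 16S
    references whose lineage rides in the description).
    """
    with _open(path) as handle:
        for index, (title, seq) in enumerate(SimpleFastaParser(handle)):
            if not title:
                raise FastqParseError(f"record {index}: empty FASTA title")
            token = title.split()[0]
            ident, tags = parse_tags(token)
            rec = SeqRecord(ident, seq.upper(), None, tags)
            if keep_description:
                rec.description = title[len(token):].strip()  # type: ignore[attr-defined]
            yield rec


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> int:
    n = 0
    with _open(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.header}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")
            n += 1
    return n


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized mate pairs from two FASTQ files.

    Raises :class:`PairingError` when ids at the same position disagree and
    when one file is longer than the other.
    """
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for index, (r1, r2) in enumerate(zip(it1, it2)):
        try:
            yield ReadPair(r1, r2)
        except PairingError as exc:
            raise PairingError(f"pair {index}: {exc}") from exc
    leftover = next(it1, None) or next(it2, None)
    if leftover is not None:
        raise PairingError(f"unpaired trailing read {leftover.id!r}")


# ---------------------------------------------------------------------------
# abundance matrices


class AbundanceMatrix:
    """Features x samples table of non-negative counts.

    Thin wrapper over a pandas DataFrame (features on the index, samples on
    the columns) enforcing the invariants: unique feature ids, unique sample
    names, all entries >= 0.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValueError("duplicate feature ids in abundance matrix")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample names in abundance matrix")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative counts in abundance matrix")
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "feature"
        df.columns = df.columns.astype(str)
        self.df = df

    @classmethod
    def from_dict(cls, data: dict[str, dict[str, float]], samples: list[str] | None = None) -> "AbundanceMatrix":
        """Build from ``{feature: {sample: count}}``; missing cells are 0."""
        df = pd.DataFrame.from_dict(data, orient="index").fillna(0)
        if samples is not None:
            df = df.reindex(columns=samples, fill_value=0)
        return cls(df)

    @property
    def features(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def equals(self, other: "AbundanceMatrix") -> bool:
        if self.shape != other.shape:
            return False
        if self.features != other.features or self.samples != other.samples:
            return False
        return bool((self.df.to_numpy() == other.df.to_numpy()).all())

    def __repr__(self) -> str:
        return f"AbundanceMatrix({self.shape[0]} features x {self.shape[1]} samples)"


def write_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a TSV with a leading ``feature`` column, one column per sample."""
    matrix.df.to_csv(path, sep="\t", index_label="feature")


def read_matrix(path: str | Path) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature")
    df.index = df.index.astype(str)
    return AbundanceMatrix(df)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a gene annotation map TSV: gene_id, og_id, ko_id, category.

    Empty fields mean "unannotated".  Returns a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0,
        dtype=str,
        keep_default_na=False,
        names=["gene_id", "og_id", "ko_id", "category"],
    )
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation map")
    return df.set_index("gene_id")


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
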