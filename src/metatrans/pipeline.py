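"""End-to-end orchestration of the four pipeline stages.

``run_all`` executes QC -> sorting -> (merge -> functional annotation) and
(merge -> taxonomic profiling) for every sample in a config, writes the
per-stage FASTQ/TSV outputs, and returns a run report with per-sample
survival counts.  A single global seed fans out deterministically to
per-stage seeds so re-running a config reproduces every output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import function_annot, preprocess, rna_sort, seqio, taxprofile
from .rna_sort import RnaCategory

log = logging.getLogger("metatrans")

_RRNA_KEYS = {
    "ssu": RnaCategory.SSU,
    "lsu": RnaCategory.LSU,
    "fives": RnaCategory.FIVE_S,
    "trna": RnaCategory.TRNA,
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    samples: list[tuple[str, Path, Path]]
    out_dir: Path
    rrna_refs: dict[str, Path] = field(default_factory=dict)
    catalog: Path | None = None
    annotations: Path | None = None
    ref16s: Path | None = None
    min_phred: int = 10
    min_len: int = 30
    min_overlap: int = 8
    max_diff: float = 0.10
    sort_k: int = 15
    sort_min_frac: float = 0.25
    min_orf_len: int = 60
    cluster_min_id: float = 95.0
    cluster_min_cov: float = 0.90
    map_min_id: float = 90.0
    map_min_cov: float = 0.80
    otu_min_id: float = 97.0
    subsample: int = 100_000
    rarefy_depth: int = 1952
    min_taxon_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        if not self.samples:
            raise ValueError("config lists no samples")
        for name, fq1, fq2 in self.samples:
            for path in (fq1, fq2):
                if not Path(path).exists():
                    raise FileNotFoundError(f"sample {name!r}: missing file {path}")
        for key, path in self.rrna_refs.items():
            if key not in _RRNA_KEYS:
                raise ValueError(f"unknown rRNA reference key {key!r}")
            if not Path(path).exists():
                raise FileNotFoundError(f"rRNA reference {key!r}: missing file {path}")
        for label, path in (("catalog", self.catalog), ("annotations", self.annotations), ("ref16s", self.ref16s)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: missing file {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key/value YAML config (see README for the dialect)."""
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        samples = [
            (s["name"], Path(s["fastq1"]), Path(s["fastq2"]))
            for s in raw.pop("samples", [])
        ]
        refs = {k: Path(v) for k, v in (raw.pop("rrna_refs", {}) or {}).items()}
        for key in ("catalog", "annotations", "ref16s"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        out_dir = Path(raw.pop("out_dir", "metatrans_out"))
        return cls(samples=samples, out_dir=out_dir, rrna_refs=refs, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Fixed derivation of a per-stage seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the full pipeline for every sample; returns the run report.

    Stage outputs land under ``cfg.out_dir``; the report (also written as
    ``report.json``) records per-sample read counts surviving each stage
    and all parameters.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trim = preprocess.TrimPolicy(cfg.min_phred, cfg.min_len)
    merge = preprocess.MergePolicy(cfg.min_overlap, cfg.max_diff)
    index = rna_sort.build_index(
        {_RRNA_KEYS[k]: v for k, v in cfg.rrna_refs.items()}, k=cfg.sort_k
    )
    catalog = None
    annotations = None
    if cfg.catalog is not None:
        if cfg.annotations is not None:
            annotations = seqio.read_annotations(cfg.annotations)
        catalog = function_annot.CatalogIndex.from_fasta(cfg.catalog, annotations)
    reference16s = (
        taxprofile.Reference16S.from_fasta(cfg.ref16s) if cfg.ref16s else None
    )

    report: dict[str, Any] = {"parameters": _parameters(cfg), "samples": {}}
    hits_by_sample: dict[str, list] = {}
    queries_by_sample: dict[str, list] = {}
    assignments: dict[str, list] = {}

    for name, fq1, fq2 in cfg.samples:
        t0 = time.time()
        try:
            counts = _run_sample(
                name, fq1, fq2, cfg, trim, merge, index, catalog, reference16s,
                out, hits_by_sample, queries_by_sample, assignments,
            )
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            raise RuntimeError(f"sample {name!r}: {exc}") from exc
        counts["wall_seconds"] = round(time.time() - t0, 3)
        report["samples"][name] = counts
        log.info("sample=%s %s", name, counts)

    if catalog is not None and hits_by_sample:
        matrix = function_annot.aggregate_counts(hits_by_sample, queries_by_sample)
        seqio.write_matrix(matrix, out / "genes.tsv")
        if annotations is not None:
            og, cat = function_annot.rollup(matrix, annotations)
            seqio.write_matrix(og, out / "og.tsv")
            seqio.write_matrix(cat, out / "categories.tsv")
    if reference16s is not None and assignments:
        tables = taxprofile.build_rank_tables(assignments)
        for rank, table in tables.items():
            seqio.write_matrix(table, out / f"rank_{rank}.tsv")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _parameters(cfg: PipelineConfig) -> dict[str, Any]:
    params = {}
    for key, value in vars(cfg).items():
        if key == "samples":
            params[key] = [[n, str(a), str(b)] for n, a, b in cfg.samples]
        elif isinstance(value, dict):
            params[key] = {k: str(v) for k, v in value.items()}
        elif isinstance(value, Path):
            params[key] = str(value)
        else:
            params[key] = value
    return params


def _run_sample(
    name, fq1, fq2, cfg, trim, merge, index, catalog, reference16s,
    out: Path, hits_by_sample, queries_by_sample, assignments,
) -> dict[str, Any]:
    pairs = list(seqio.read_fastq_pairs(fq1, fq2))
    kept, orphans = preprocess.filter_pairs(pairs, trim)
    collapsed = preprocess.collapse_pairs(kept)
    seqio.write_fastq((p.r1 for p in collapsed), out / f"{name}_hq_1.fastq")
    seqio.write_fastq((p.r2 for p in collapsed), out / f"{name}_hq_2.fastq")

    buckets = rna_sort.sort_sample(collapsed, index, cfg.sort_min_frac)
    counts: dict[str, Any] = {
        "raw_pairs": len(pairs),
        "hq_pairs": len(kept),
        "orphans": orphans,
        "collapsed_pairs": len(collapsed),
    }
    for category, bucket in buckets.items():
        counts[f"pairs_{category.value}"] = sum(p.r1.copies for p in bucket)

    mrna = buckets[RnaCategory.MRNA]
    merged, unmerged = preprocess.merge_sample(mrna, merge)
    counts["mrna_merged"] = len(merged)
    counts["mrna_unmerged"] = len(unmerged)
    if catalog is not None:
        hits, reps, fstats = function_annot.quantify_functional(
            merged, unmerged, catalog,
            cfg.min_orf_len, cfg.cluster_min_id, cfg.cluster_min_cov,
            cfg.map_min_id, cfg.map_min_cov,
        )
        hits_by_sample[name] = hits
        queries_by_sample[name] = reps
        counts.update({f"function_{k}": v for k, v in fstats.items()})

    if reference16s is not None:
        rrna_pairs = [
            p
            for cat in (RnaCategory.SSU, RnaCategory.LSU, RnaCategory.FIVE_S, RnaCategory.TRNA)
            for p in buckets[cat]
        ]
        rmerged, runmerged = preprocess.merge_sample(rrna_pairs, merge)
        reads = list(rmerged) + [p.r1 for p in runmerged]
        sample_assign, unclassified = taxprofile.profile_sample(
            reads,
            reference16s,
            subsample=cfg.subsample,
            seed=stage_seed(cfg.seed, f"subsample:{name}"),
            cluster_min_id=cfg.otu_min_id,
            map_min_id=cfg.map_min_id,
            map_min_cov=cfg.map_min_cov,
        )
        assignments[name] = sample_assign
        counts["taxonomy_assigned"] = sum(w for _, w in sample_assign)
        counts["taxonomy_unclassified"] = unclassified
    return counts
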