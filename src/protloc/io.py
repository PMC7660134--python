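"""Readers and writers for the on-disk formats used across the pipeline.

All genomic coordinates are 0-based half-open internally (BED-native); BED6
on disk for crosslinks (score = deduplicated count) and BED6+3 for clusters
(extra columns: sum, max_density, min_density); a GTF-lite tab format for
transcript annotation; TSV for count tables and all result tables; FASTQ
(via Biopython) for synthetic iCLIP reads.  Every reader/writer pair is a
round-trip identity on its own output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CountTable",
    "GenomeAnnotation",
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "read_bed",
    "write_bed",
    "read_annotation",
    "write_annotation",
    "read_fastq",
    "write_fastq",
    "file_sha256",
]

COMPARTMENTS = ("protrusion", "body")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
BED_EXTRA = ["sum", "max_density", "min_density"]

ANNOTATION_COLUMNS = ["gene_id", "region_role", "chrom", "start", "end", "strand"]
REGION_ROLES = ("five_prime_utr", "orf", "three_prime_utr", "intron")


@dataclass
class CountTable:
    """Gene-level counts for paired subcellular fractions.

    ``counts`` is a feature-indexed DataFrame of non-negative integers; the
    ``design`` maps each column to (sample_id, compartment).
    """

    counts: pd.DataFrame
    design: pd.DataFrame  # columns: column, sample_id, compartment

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        if set(self.design["column"]) != set(self.counts.columns):
            raise ValueError("design does not match count columns")
        bad = set(self.design["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def columns_for(self, compartment: str) -> list[str]:
        sel = self.design[self.design["compartment"] == compartment]
        return list(sel["column"])


def _design_from_suffixes(columns: Iterable[str]) -> pd.DataFrame:
    """Infer (sample, compartment) from column names like 'S1_protrusion'."""
    rows = []
    for col in columns:
        stem, _, suffix = col.rpartition("_")
        if suffix not in COMPARTMENTS or not stem:
            raise ValueError(
                f"column {col!r} lacks a _protrusion/_body suffix and no design file was given"
            )
        rows.append({"column": col, "sample_id": stem, "compartment": suffix})
    return pd.DataFrame(rows)


def read_count_table(path, design_path=None) -> CountTable:
    """Read a TSV count table (first column = feature_id).

    Compartment labels come from a sidecar design TSV (columns: column,
    sample_id, compartment) or, failing that, from a ``_protrusion`` /
    ``_body`` column-name suffix.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"no features in {path}") from None
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"no features in {path}")
    df = df.set_index(df.columns[0])
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id: {dup[0]!r}")
    counts = df.astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", dtype=str)
    else:
        design = _design_from_suffixes(counts.columns)
    return CountTable(counts=counts, design=design)


def write_count_table(table: CountTable, path, design_path=None) -> None:
    out = table.counts.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t")
    if design_path is not None:
        table.design.to_csv(design_path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED6 (or BED6+3 when cluster columns are present), sorted.

    ``intervals`` needs columns chrom/start/end/strand and optionally
    name/score plus the cluster extras (sum, max_density, min_density).
    Intervals are 0-based half-open; ``end <= start`` is an error.
    """
    df = intervals.copy()
    if df.empty:
        cols = BED_COLUMNS + [c for c in BED_EXTRA if c in df.columns]
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", header=False, index=False)
        return
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"interval with end <= start at {bad['chrom']}:{bad['start']}")
    if "name" not in df.columns:
        df["name"] = "."
    if "score" not in df.columns:
        df["score"] = 0
    extras = [c for c in BED_EXTRA if c in df.columns]
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    cols = BED_COLUMNS + extras
    df[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_bed(path) -> pd.DataFrame:
    """Read BED6 or BED6+3 back into the internal interval frame."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    ncol = df.shape[1]
    cols = BED_COLUMNS + BED_EXTRA[: max(0, ncol - 6)]
    df.columns = cols[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


@dataclass
class GenomeAnnotation:
    """Transcript regions with roles, strand-aware, 0-based half-open.

    ``regions``: DataFrame(gene_id, region_role, chrom, start, end, strand).
    TSS and ORF-start landmarks are derived from the regions per gene.
    """

    regions: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = self.regions
        missing = set(ANNOTATION_COLUMNS) - set(r.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        bad_roles = set(r["region_role"]) - set(REGION_ROLES)
        if bad_roles:
            raise ValueError(f"unknown region roles: {sorted(bad_roles)}")
        if (r["start"] < 0).any() or (r["end"] <= r["start"]).any():
            raise ValueError("regions must be 0-based half-open with end > start")
        for gid, grp in r.groupby("gene_id"):
            if grp["strand"].nunique() > 1:
                raise ValueError(f"gene {gid!r} mixes strands")
            iv = grp.sort_values("start")
            if (iv["start"].to_numpy()[1:] < iv["end"].to_numpy()[:-1]).any():
                raise ValueError(f"gene {gid!r} has overlapping regions")

    def gene_strand(self, gene_id: str) -> str:
        return str(self.regions.loc[self.regions["gene_id"] == gene_id, "strand"].iloc[0])

    def tss(self) -> pd.DataFrame:
        """Per-gene transcription start: 5'-most position, strand-aware."""
        rows = []
        for gid, grp in self.regions.groupby("gene_id"):
            strand = grp["strand"].iloc[0]
            chrom = grp["chrom"].iloc[0]
            pos = int(grp["start"].min()) if strand == "+" else int(grp["end"].max()) - 1
            rows.append({"gene_id": gid, "chrom": chrom, "position": pos, "strand": strand})
        return pd.DataFrame(rows)

    def orf_starts(self) -> pd.DataFrame:
        """Per-gene translation start: 5'-most ORF position, strand-aware."""
        rows = []
        orf = self.regions[self.regions["region_role"] == "orf"]
        for gid, grp in orf.groupby("gene_id"):
            strand = grp["strand"].iloc[0]
            chrom = grp["chrom"].iloc[0]
            pos = int(grp["start"].min()) if strand == "+" else int(grp["end"].max()) - 1
            rows.append({"gene_id": gid, "chrom": chrom, "position": pos, "strand": strand})
        return pd.DataFrame(rows)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    annotation.regions[ANNOTATION_COLUMNS].sort_values(
        ["chrom", "start", "end", "gene_id"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path, chrom_sizes=None) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return GenomeAnnotation(regions=df, chrom_sizes=dict(chrom_sizes or {}))


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    records = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


@dataclass
class RunConfig:
    """Run-level configuration: seed, thresholds, and paths.

    Defaults reproduce the published analysis parameters: enrichment FDR
    0.02, meta-analysis/volcano FDR 0.05, Paraclu min_sum 10 / max_len 200 /
    min fold 2, CPM pseudocount 1, min summed raw count 10.
    """

    seed: int = 0
    fdr_enrichment: float = 0.02
    fdr_meta: float = 0.05
    min_members: int = 5
    pseudocount: float = 1.0
    min_count: int = 10
    paraclu_min_sum: float = 10.0
    paraclu_max_len: int = 200
    paraclu_min_fold: float = 2.0
    top_window: int = 15
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
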