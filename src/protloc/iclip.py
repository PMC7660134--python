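"""iCLIP analysis: from barcoded reads to specific binding sites.

The chain follows the standard truncation-based iCLIP workflow: demultiplex
reads on a 5-nt experimental barcode embedded in a WWW+barcode+NNNN prefix
(the 3+4 random nucleotides form the 7-nt UMI), define the crosslink site
as the nucleotide immediately 5' of the cDNA insert start (where reverse
transcription truncated), collapse PCR duplicates by (position, UMI),
merge replicate tracks, call density clusters with a Paraclu-style
parametric clustering, subtract control (e.g. GFP-only) peaks to obtain
specific binding sites, and summarize them as target genes, region
distributions and landmark metaprofiles.

Cluster semantics
-----------------
For an interval of crosslink sites, define its *cohesion* as the minimum
density (summed count / spanned nucleotides, half-open coordinates) over
all of its prefixes and suffixes, the interval itself included.  An
interval is a cluster exactly when its cohesion strictly exceeds the
cohesion of every strictly containing interval on the same chrom/strand
track: it is then the maximal interval for every density threshold in
(min_density, max_density], where max_density is its own cohesion and
min_density the largest cohesion among containing intervals (0 for the
track-wide root, whose stability fold is taken as infinite).  Reported
clusters additionally satisfy sum >= min_sum, length <= max_len and
max_density/min_density >= min_density_increase; overlapping survivors are
resolved by keeping the higher fold (ties: shorter, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomeAnnotation

__all__ = [
    "BarcodeScheme",
    "CrosslinkTrack",
    "demultiplex",
    "assign_crosslinks",
    "dedup_umi",
    "merge_tracks",
    "paraclu",
    "subtract_control",
    "call_targets",
    "region_distribution",
    "metaprofile",
]

EVENT_COLUMNS = ["read_id", "chrom", "position", "strand", "umi", "sample_id"]
TRACK_COLUMNS = ["chrom", "position", "strand", "count"]
CLUSTER_COLUMNS = [
    "chrom", "start", "end", "strand", "sum", "max_density", "min_density", "fold",
]

PREFIX_LEN = 12  # 3 random (W) + 5 barcode + 4 random


@dataclass
class BarcodeScheme:
    """Read-prefix layout: 3 random W nucleotides, 5-nt barcode, 4 random.

    ``barcodes`` maps each 5-nt barcode to its sample id; the optional
    adapter is the downstream constant sequence (not used for matching).
    """

    barcodes: Mapping[str, str]
    adapter: str = ""

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("barcode map is empty")
        for bc in self.barcodes:
            if len(bc) != 5:
                raise ValueError(f"barcode {bc!r} is not 5 nt")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be pairwise distinct")
        samples = list(self.barcodes.values())
        if len(set(samples)) != len(samples):
            raise ValueError("two barcodes map to the same sample")


def demultiplex(
    reads: Iterable[tuple[str, str]], scheme: BarcodeScheme
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Split reads by exact 5-nt barcode match; attach and trim the UMI.

    The UMI is the concatenation of prefix positions 1-3 and 9-12 (7 nt);
    barcode and UMI are trimmed from the emitted insert.  Reads shorter
    than the 12-nt prefix or with an unknown barcode go to the unassigned
    bin with a reason.  assigned + unassigned always partitions the input.
    """
    per_sample: dict[str, list] = {s: [] for s in scheme.barcodes.values()}
    unassigned = []
    for rid, seq in reads:
        if len(seq) < PREFIX_LEN:
            unassigned.append((rid, seq, "shorter_than_prefix"))
            continue
        umi = seq[0:3] + seq[8:12]
        barcode = seq[3:8]
        sample = scheme.barcodes.get(barcode)
        if sample is None:
            unassigned.append((rid, seq, "unknown_barcode"))
            continue
        per_sample[sample].append((rid, umi, seq[PREFIX_LEN:]))
    out = {
        s: pd.DataFrame(rows, columns=["read_id", "umi", "insert"])
        for s, rows in per_sample.items()
    }
    return out, pd.DataFrame(unassigned, columns=["read_id", "sequence", "reason"])


def assign_crosslinks(
    alignments: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None
) -> tuple[pd.DataFrame, int]:
    """Crosslink events from insert alignments (0-based half-open).

    The crosslink is the nucleotide 5' of the insert on the read's strand:
    position = start - 1 on '+', position = end on '-'.  Events falling
    outside the chromosome are dropped and counted.

    Returns (events, n_dropped).
    """
    df = alignments.copy()
    plus = df["strand"] == "+"
    df["position"] = np.where(plus, df["start"] - 1, df["end"]).astype(np.int64)
    keep = df["position"] >= 0
    if chrom_sizes:
        sizes = df["chrom"].map(dict(chrom_sizes))
        keep &= df["position"] < sizes.fillna(np.inf)
    dropped = int((~keep).sum())
    cols = [c for c in EVENT_COLUMNS if c in df.columns or c == "position"]
    events = df.loc[keep, [c for c in cols if c in df.columns]].reset_index(drop=True)
    return events, dropped


@dataclass
class CrosslinkTrack:
    """Strand-aware per-position deduplicated crosslink counts."""

    df: pd.DataFrame  # chrom, position, strand, count

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        self.df = (
            self.df[TRACK_COLUMNS]
            .astype({"position": np.int64})
            .sort_values(["chrom", "strand", "position"], kind="mergesort")
            .reset_index(drop=True)
        )
        if (self.df["count"] <= 0).any():
            raise ValueError("stored positions must have positive counts")

    @property
    def library_size(self) -> float:
        return float(self.df["count"].sum())

    def to_bed(self) -> pd.DataFrame:
        bed = self.df.rename(columns={"position": "start", "count": "score"}).copy()
        bed["end"] = bed["start"] + 1
        bed["name"] = "."
        return bed[["chrom", "start", "end", "name", "score", "strand"]]

    @classmethod
    def from_bed(cls, bed: pd.DataFrame) -> "CrosslinkTrack":
        df = bed.rename(columns={"start": "position", "score": "count"})
        return cls(df[TRACK_COLUMNS])


def dedup_umi(events: pd.DataFrame) -> CrosslinkTrack:
    """Collapse PCR duplicates: count distinct UMIs per crosslink position.

    Order-independent by construction; reads mapping to the same position
    with the same UMI collapse to one molecule.
    """
    if events.empty:
        return CrosslinkTrack(pd.DataFrame(columns=TRACK_COLUMNS))
    grouped = (
        events.groupby(["chrom", "position", "strand"], sort=True)["umi"]
        .nunique()
        .rename("count")
        .reset_index()
    )
    return CrosslinkTrack(grouped)


def merge_tracks(tracks: Sequence[CrosslinkTrack]) -> CrosslinkTrack:
    """Positionwise sum of replicate tracks (the replicate-merge step)."""
    frames = [t.df for t in tracks if not t.df.empty]
    if not frames:
        return CrosslinkTrack(pd.DataFrame(columns=TRACK_COLUMNS))
    cat = pd.concat(frames, ignore_index=True)
    merged = (
        cat.groupby(["chrom", "position", "strand"], sort=True)["count"].sum().reset_index()
    )
    return CrosslinkTrack(merged)


def _cluster_family(positions: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """All clusters of one (chrom, strand) track with their density range.

    Vectorized computation of the cohesion of every interval of consecutive
    sites (prefix/suffix running minima of the density matrix) and of the
    maximum cohesion over containing intervals (2-D running maximum), then
    selection of intervals whose cohesion strictly exceeds it.
    """
    n = positions.size
    if n == 0:
        return pd.DataFrame(columns=["a", "b", "sum", "max_density", "min_density"])
    cum = np.concatenate([[0.0], np.cumsum(values)])
    # D[a, b] = density of sites a..b inclusive; invalid (b < a) -> +inf
    sums = cum[None, 1:] - cum[:-1, None]
    spans = (positions[None, :] + 1 - positions[:, None]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = sums / spans
    invalid = np.tril(np.ones((n, n), dtype=bool), k=-1)
    D[invalid] = np.inf
    prefix_min = np.minimum.accumulate(D, axis=1)
    suffix_min = np.minimum.accumulate(D[::-1, :], axis=0)[::-1]
    coh = np.minimum(prefix_min, suffix_min)
    coh[invalid] = -np.inf
    # Q[a, b] = max cohesion over a' <= a, b' >= b
    Q = np.maximum.accumulate(coh, axis=0)
    Q = np.maximum.accumulate(Q[:, ::-1], axis=1)[:, ::-1]
    parent = np.full((n, n), -np.inf)
    parent[1:, :] = Q[:-1, :]
    parent[:, :-1] = np.maximum(parent[:, :-1], Q[:, 1:])
    members = (coh > parent) & ~invalid
    a_idx, b_idx = np.nonzero(members)
    return pd.DataFrame(
        {
            "a": a_idx,
            "b": b_idx,
            "sum": sums[a_idx, b_idx],
            "max_density": coh[a_idx, b_idx],
            "min_density": np.maximum(parent[a_idx, b_idx], 0.0),
        }
    )


def _resolve_overlaps(clusters: pd.DataFrame) -> pd.DataFrame:
    """Flatten overlapping clusters: keep higher fold, tie shorter/leftmost."""
    if clusters.empty:
        return clusters
    order = clusters.sort_values(
        by=["fold", "length", "chrom", "start", "end", "strand"],
        ascending=[False, True, True, True, True, True],
        kind="mergesort",
    )
    kept: dict[tuple, list[tuple[int, int]]] = {}
    keep_rows = []
    for idx, row in order.iterrows():
        key = (row["chrom"], row["strand"])
        accepted = kept.setdefault(key, [])
        if any(row["start"] < e and s < row["end"] for s, e in accepted):
            continue
        accepted.append((row["start"], row["end"]))
        keep_rows.append(idx)
    out = clusters.loc[keep_rows].sort_values(
        ["chrom", "start", "end", "strand"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def paraclu(
    track: CrosslinkTrack,
    min_sum: float = 10.0,
    max_len: int = 200,
    min_density_increase: float = 2.0,
    resolve_overlaps: bool = True,
) -> pd.DataFrame:
    """Parametric density clustering of a crosslink track.

    Enumerates, per (chrom, strand), the family of maximal-density clusters
    across all density thresholds (see module docstring for the exact
    semantics) and reports those with sum >= ``min_sum``, length <=
    ``max_len`` nucleotides and stability fold max_density/min_density >=
    ``min_density_increase``.  With ``resolve_overlaps`` (the default, the
    flat peak list used downstream) overlapping survivors keep the higher
    fold.
    """
    if min_sum <= 0 or max_len <= 0 or min_density_increase <= 0:
        raise ValueError("paraclu parameters must be positive")
    rows = []
    for (chrom, strand), grp in track.df.groupby(["chrom", "strand"], sort=True):
        pos = grp["position"].to_numpy()
        val = grp["count"].to_numpy(dtype=float)
        fam = _cluster_family(pos, val)
        if fam.empty:
            continue
        fam["chrom"] = chrom
        fam["strand"] = strand
        fam["start"] = pos[fam["a"]]
        fam["end"] = pos[fam["b"]] + 1
        rows.append(fam.drop(columns=["a", "b"]))
    if not rows:
        return pd.DataFrame(columns=CLUSTER_COLUMNS + ["length"])
    fam = pd.concat(rows, ignore_index=True)
    fam["length"] = fam["end"] - fam["start"]
    with np.errstate(divide="ignore"):
        fam["fold"] = np.where(
            fam["min_density"] > 0, fam["max_density"] / fam["min_density"], np.inf
        )
    fam = fam[
        (fam["sum"] >= min_sum)
        & (fam["length"] <= max_len)
        & (fam["fold"] >= min_density_increase)
    ].reset_index(drop=True)
    fam = fam[CLUSTER_COLUMNS + ["length"]]
    if resolve_overlaps:
        fam = _resolve_overlaps(fam)
    return fam.sort_values(["chrom", "start", "end", "strand"]).reset_index(drop=True)


def _overlaps_any(peaks: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Strand-aware any-overlap (>= 1 nt) of each peak with a peak set."""
    flags = np.zeros(len(peaks), dtype=bool)
    by_key: dict[tuple, np.ndarray] = {}
    for key, grp in others.groupby(["chrom", "strand"], sort=False):
        by_key[key] = grp[["start", "end"]].to_numpy()
    for i, row in enumerate(peaks.itertuples(index=False)):
        ivs = by_key.get((row.chrom, row.strand))
        if ivs is None:
            continue
        flags[i] = bool(np.any((row.start < ivs[:, 1]) & (ivs[:, 0] < row.end)))
    return flags


def subtract_control(peaks: pd.DataFrame, control_peaks: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove peaks overlapping a control peak by >= 1 nt on the same strand.

    bedtools-intersect ``-v`` semantics.  Returns (specific_peaks, n_removed).
    """
    if peaks.empty or control_peaks.empty:
        return peaks.reset_index(drop=True), 0
    hit = _overlaps_any(peaks, control_peaks)
    return peaks[~hit].reset_index(drop=True), int(hit.sum())


def call_targets(
    specific_peaks: pd.DataFrame, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target genes: any gene with at least one specific binding site.

    A peak is assigned to a gene when it overlaps any of the gene's regions
    (exonic or intronic) on the same strand; a peak spanning two genes'
    overlapping regions is assigned to both and flagged ambiguous; peaks
    overlapping no gene are counted intergenic.

    Returns (targets, peak_assignments) where targets has per-gene peak
    counts and peak_assignments records gene_id (or "intergenic") and an
    ambiguity flag per peak.
    """
    gene_ivs = []
    for gid, grp in annotation.regions.groupby("gene_id"):
        for row in grp.itertuples(index=False):
            gene_ivs.append((row.chrom, row.strand, row.start, row.end, gid))
    assignments = []
    for i, pk in enumerate(specific_peaks.itertuples(index=False)):
        genes = sorted(
            {
                gid
                for chrom, strand, s, e, gid in gene_ivs
                if chrom == pk.chrom and strand == pk.strand and pk.start < e and s < pk.end
            }
        )
        if not genes:
            assignments.append((i, "intergenic", False))
        else:
            for g in genes:
                assignments.append((i, g, len(genes) > 1))
    assign = pd.DataFrame(assignments, columns=["peak_index", "gene_id", "ambiguous"])
    genic = assign[assign["gene_id"] != "intergenic"]
    targets = (
        genic.groupby("gene_id")["peak_index"].nunique().rename("n_peaks").reset_index()
    )
    return targets.sort_values("gene_id").reset_index(drop=True), assign


REGION_CATEGORIES = ["five_prime_top", "five_prime_utr", "orf", "three_prime_utr", "intron"]


def region_distribution(
    specific_peaks: pd.DataFrame,
    annotation: GenomeAnnotation,
    top_window: int = 15,
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of binding sites per transcript region.

    Each peak is assigned one category by its midpoint: the 5'TOP window
    (first ``top_window`` nt downstream of the TSS, strand-aware) takes
    precedence, then the transcript region role containing the midpoint.
    Fractions are over classified peaks and sum to 1; peaks whose midpoint
    falls outside any annotated region are reported as intergenic in the
    per-peak table and excluded from the fractions.
    """
    if top_window < 1:
        raise ValueError("top_window must be >= 1")
    tss = annotation.tss()
    rows = []
    for i, pk in enumerate(specific_peaks.itertuples(index=False)):
        mid = (pk.start + pk.end) // 2
        category = None
        for t in tss.itertuples(index=False):
            if t.chrom != pk.chrom or t.strand != pk.strand:
                continue
            if t.strand == "+" and t.position <= mid < t.position + top_window:
                category = "five_prime_top"
                break
            if t.strand == "-" and t.position - top_window < mid <= t.position:
                category = "five_prime_top"
                break
        if category is None:
            hits = annotation.regions[
                (annotation.regions["chrom"] == pk.chrom)
                & (annotation.regions["strand"] == pk.strand)
                & (annotation.regions["start"] <= mid)
                & (mid < annotation.regions["end"])
            ]
            if len(hits):
                category = str(hits.sort_values(["gene_id"]).iloc[0]["region_role"])
            else:
                category = "intergenic"
        rows.append((i, mid, category))
    per_peak = pd.DataFrame(rows, columns=["peak_index", "midpoint", "category"])
    classified = per_peak[per_peak["category"] != "intergenic"]
    if classified.empty:
        fractions = pd.Series(0.0, index=REGION_CATEGORIES)
    else:
        counts = classified["category"].value_counts()
        fractions = counts.reindex(REGION_CATEGORIES).fillna(0.0) / counts.sum()
    return fractions, per_peak


def metaprofile(
    track: CrosslinkTrack,
    landmarks: pd.DataFrame,
    window: int = 50,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Library-size normalized crosslink metaprofile around aligned landmarks.

    ``landmarks`` needs columns chrom, position, strand.  Counts are summed
    across landmarks in strand-oriented offset coordinates (offset > 0 is
    downstream of the landmark on its strand, 1-nt bins), divided by the
    track's library size and scaled to counts per million.  Landmarks closer
    than ``window`` to a contig edge are truncated and flagged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(landmarks) == 0:
        raise ValueError("need at least one landmark")
    lib = track.library_size
    offsets = np.arange(-window, window + 1)
    profile = np.zeros(offsets.size, dtype=float)
    lookup = {
        key: dict(zip(grp["position"], grp["count"]))
        for key, grp in track.df.groupby(["chrom", "strand"], sort=False)
    }
    truncated = []
    for lm in landmarks.itertuples(index=False):
        counts = lookup.get((lm.chrom, lm.strand), {})
        genomic = lm.position + offsets if lm.strand == "+" else lm.position - offsets
        valid = genomic >= 0
        if chrom_sizes and lm.chrom in dict(chrom_sizes):
            valid &= genomic < dict(chrom_sizes)[lm.chrom]
        if not valid.all():
            truncated.append((lm.chrom, lm.position, lm.strand))
        for k, g in zip(np.nonzero(valid)[0], genomic[valid]):
            c = counts.get(int(g))
            if c:
                profile[k] += c
    value = profile / lib * 1e6 if lib > 0 else profile
    out = pd.DataFrame({"offset": offsets, "value": value})
    out.attrs["truncated_landmarks"] = truncated
    return out
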