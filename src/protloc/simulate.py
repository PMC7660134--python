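"""Synthetic datasets with planted, recorded ground truth.

Every generator emulates one of the pipeline's input types — paired
protrusion/cell-body 3' mRNA-seq counts, multi-line log2 ratio panels,
pulsed-SILAC triplets, barcoded iCLIP reads over a pseudo-genome, and
RNA-FISH spot fields — and returns the dataset together with a TruthRecord
sufficient to score recovery of the planted effect.  The same seed always
reproduces byte-identical output.

Default condition choices (negative-binomial counts with dispersion 0.1 and
mean ~200, 5,000 genes with an 80-gene shifted category, 6-sample ratio
panels with sd 0.3, reciprocal pulsed-SILAC replicates, 0.8 nuclear
fraction for nascent versus 0.4 for old protein) mirror the study design
the pipeline targets; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iclip import BarcodeScheme
from .imaging import SpotField
from .io import CountTable, GenomeAnnotation

from shapely.geometry import Polygon, box

__all__ = [
    "TruthRecord",
    "gen_compartment_counts",
    "gen_ratio_panel",
    "gen_pulsed_silac",
    "gen_iclip_reads",
    "gen_spot_field",
    "SimulatedIclip",
]


@dataclass
class TruthRecord:
    """Planted ground truth serialized next to each generated dataset."""

    kind: str
    seed: int
    params: dict
    table: pd.DataFrame

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n# seed={self.seed}\n")
            for k in sorted(self.params):
                fh.write(f"# {k}={self.params[k]}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _resolve_members(universe: list[str], category, rng) -> list[str]:
    if isinstance(category, (int, np.integer)):
        if category > len(universe):
            raise ValueError("category size exceeds number of features")
        idx = rng.choice(len(universe), size=int(category), replace=False)
        return [universe[i] for i in sorted(idx)]
    members = list(category)
    unknown = set(members) - set(universe)
    if unknown:
        raise ValueError(f"category members outside universe: {sorted(unknown)[:3]}")
    if len(members) > len(universe):
        raise ValueError("category size exceeds number of features")
    return members


def gen_compartment_counts(
    n_genes: int = 5000,
    category=80,
    delta: float = 1.0,
    dispersion: float = 0.1,
    lib_sizes: tuple[float, float] | None = None,
    mean_count: float = 200.0,
    seed: int = 0,
) -> tuple[CountTable, TruthRecord]:
    """Paired protrusion/body negative-binomial counts with a planted shift.

    Genes in the category have expected log2(protrusion/body) = ``delta``
    (applied symmetrically, +delta/2 and -delta/2), all others 0.  Counts
    are NB(mean, dispersion); per-gene base means are log-normal around
    ``mean_count``.  ``lib_sizes`` optionally rescales each column's
    expected total.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    members = _resolve_members(genes, category, rng)
    if n_genes < len(members):
        raise ValueError("n_genes must be >= category size")
    shift = pd.Series(0.0, index=genes)
    shift.loc[members] = delta
    base = rng.lognormal(mean=np.log(mean_count), sigma=1.0, size=n_genes)
    mu_p = base * np.power(2.0, shift.to_numpy() / 2.0)
    mu_b = base * np.power(2.0, -shift.to_numpy() / 2.0)
    if lib_sizes is not None:
        mu_p *= lib_sizes[0] / mu_p.sum()
        mu_b *= lib_sizes[1] / mu_b.sum()
    r = 1.0 / dispersion
    counts = pd.DataFrame(
        {
            "s1_protrusion": rng.negative_binomial(r, r / (r + mu_p)),
            "s1_body": rng.negative_binomial(r, r / (r + mu_b)),
        },
        index=pd.Index(genes, name="feature_id"),
    )
    design = pd.DataFrame(
        {
            "column": ["s1_protrusion", "s1_body"],
            "sample_id": ["s1", "s1"],
            "compartment": ["protrusion", "body"],
        }
    )
    truth = TruthRecord(
        kind="compartment_counts",
        seed=seed,
        params={
            "n_genes": n_genes,
            "delta": delta,
            "dispersion": dispersion,
            "mean_count": mean_count,
        },
        table=pd.DataFrame({"feature_id": members, "delta": delta}),
    )
    return CountTable(counts=counts, design=design), truth


def gen_ratio_panel(
    n_features: int = 2000,
    n_samples: int = 6,
    enriched_set=100,
    delta: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    prefix: str = "p",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-feature log2 ratio panel across samples with a planted enrichment.

    Features in the enriched set draw from Normal(delta, noise_sd) in every
    sample; all others from Normal(0, noise_sd).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    feats = _gene_ids(n_features, prefix=prefix)
    members = _resolve_members(feats, enriched_set, rng)
    mu = pd.Series(0.0, index=feats)
    mu.loc[members] = delta
    data = rng.normal(loc=mu.to_numpy()[:, None], scale=noise_sd, size=(n_features, n_samples))
    panel = pd.DataFrame(
        data,
        index=pd.Index(feats, name="feature_id"),
        columns=[f"line{j+1}" for j in range(n_samples)],
    )
    truth = TruthRecord(
        kind="ratio_panel",
        seed=seed,
        params={"n_features": n_features, "n_samples": n_samples, "delta": delta,
                "noise_sd": noise_sd},
        table=pd.DataFrame({"feature_id": members, "delta": delta}),
    )
    return panel, truth


def _fractions(nuclear: float, membrane_share: float = 0.02) -> np.ndarray:
    """(nucleus, cytosol, membrane) fractions given the nuclear fraction."""
    rest = 1.0 - nuclear
    return np.array([nuclear, rest * (1.0 - membrane_share), rest * membrane_share])


def gen_pulsed_silac(
    n_proteins: int = 1000,
    rp_set=80,
    rate_delta: float = 0.3,
    compartments: Sequence[str] = ("nucleus", "cytosol", "membrane"),
    nuclear_frac_nascent: float = 0.8,
    nuclear_frac_old: float = 0.4,
    ratio_sd: float = 0.25,
    dirichlet_conc: float = 150.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Pulsed-SILAC triplets with planted translation and localization effects.

    Returns (whole_cell, compartment_ibaq, truth):

    - ``whole_cell``: two reciprocally labeled replicates of H/M intensity
      triplets; proteins in the RP set carry a planted log2 open/closed
      translation-rate shift of ``rate_delta``, others 0.
    - ``compartment_ibaq``: per-compartment iBAQ triplets in which the
      nascent labels (M, H) of RP-set proteins place ``nuclear_frac_nascent``
      of their signal in the nucleus versus ``nuclear_frac_old`` for the
      pre-existing (L) pool; membrane share is kept near zero.  Non-RP
      proteins use a neutral (0.3, 0.5, 0.2) split for all labels.
    """
    if len(compartments) == 0:
        raise ValueError("compartments must be non-empty")
    for frac in (nuclear_frac_nascent, nuclear_frac_old):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prots = _gene_ids(n_proteins, prefix="P")
    members = _resolve_members(prots, rp_set, rng)
    is_rp = pd.Series(False, index=prots)
    is_rp.loc[members] = True

    true_ratio = np.where(is_rp.to_numpy(), rate_delta, 0.0)
    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n_proteins)
    old_pool = rng.lognormal(mean=np.log(3e6), sigma=1.0, size=n_proteins)
    whole_rows = []
    for rep, scheme in (("rep1", "H_open"), ("rep2", "M_open")):
        obs = true_ratio + rng.normal(0.0, ratio_sd, size=n_proteins)
        closed = base * rng.lognormal(0.0, 0.1, size=n_proteins)
        open_i = closed * np.power(2.0, obs)
        h, m = (open_i, closed) if scheme == "H_open" else (closed, open_i)
        whole_rows.append(
            pd.DataFrame(
                {
                    "protein_id": prots,
                    "intensity_L": old_pool,
                    "intensity_M": m,
                    "intensity_H": h,
                    "compartment": "whole",
                    "replicate_id": rep,
                    "label_scheme": scheme,
                }
            )
        )
    whole_cell = pd.concat(whole_rows, ignore_index=True)

    comp_arr = list(compartments)
    neutral = np.array([0.3, 0.5, 0.2])[: len(comp_arr)]
    neutral = neutral / neutral.sum()
    ibaq_rows = []
    totals = {lab: rng.lognormal(mean=np.log(1e6), sigma=0.8, size=n_proteins)
              for lab in ("L", "M", "H")}
    for i, pid in enumerate(prots):
        fr = {}
        for lab in ("L", "M", "H"):
            if is_rp.iloc[i] and set(comp_arr) >= {"nucleus", "cytosol"}:
                nominal = _fractions(
                    nuclear_frac_old if lab == "L" else nuclear_frac_nascent
                )[: len(comp_arr)]
            else:
                nominal = neutral
            nz = nominal > 0
            sampled = np.zeros(len(comp_arr))
            if nz.sum() == 1:
                sampled[nz] = 1.0
            else:
                sampled[nz] = rng.dirichlet(dirichlet_conc * nominal[nz])
            fr[lab] = sampled * totals[lab][i]
        for j, comp in enumerate(comp_arr):
            ibaq_rows.append(
                {
                    "protein_id": pid,
                    "intensity_L": fr["L"][j],
                    "intensity_M": fr["M"][j],
                    "intensity_H": fr["H"][j],
                    "compartment": comp,
                    "replicate_id": "frac1",
                    "label_scheme": "H_open",
                }
            )
    compartment_ibaq = pd.DataFrame(ibaq_rows)
    truth = TruthRecord(
        kind="pulsed_silac",
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "rate_delta": rate_delta,
            "nuclear_frac_nascent": nuclear_frac_nascent,
            "nuclear_frac_old": nuclear_frac_old,
            "ratio_sd": ratio_sd,
        },
        table=pd.DataFrame({"protein_id": members, "rate_delta": rate_delta}),
    )
    return whole_cell, compartment_ibaq, truth


BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=n)])


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulatedIclip:
    """Synthetic iCLIP dataset: reads, true alignments and planted truth."""

    reads: list  # (read_id, sequence)
    alignments: pd.DataFrame  # read_id, chrom, start, end, strand, sample_id, umi
    truth_clusters: pd.DataFrame  # chrom, start, end, strand (BED-ready)
    genome: dict  # chrom -> sequence
    truth: TruthRecord


def gen_iclip_reads(
    cluster_spec: pd.DataFrame | None,
    barcodes: Mapping[str, str],
    n_reads: int = 10000,
    background_rate: float = 0.1,
    duplication_rate: float = 0.0,
    genome_length: int = 10000,
    insert_len: int = 30,
    annotation: GenomeAnnotation | None = None,
    seed: int = 0,
) -> SimulatedIclip:
    """Barcoded iCLIP reads over a single pseudo-chromosome.

    Crosslink sites are drawn from the planted clusters (rows with chrom,
    start, end, strand and a sampling ``weight``) with probability
    1 - ``background_rate`` and uniformly from the genome otherwise; the
    cDNA insert starts one nucleotide downstream of the crosslink on the
    site's strand.  Each read is WWW + barcode + NNNN + insert; the 3-nt W
    part draws from {A, T}.  With probability ``duplication_rate`` a read
    re-emits a previously generated (position, UMI) molecule, emulating PCR
    duplication.  Samples are assigned uniformly across the barcode map.
    """
    scheme = BarcodeScheme(barcodes)  # validates the map
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    if cluster_spec is None or len(cluster_spec) == 0:
        cluster_spec = pd.DataFrame(columns=["chrom", "start", "end", "strand", "weight"])
        if background_rate < 1.0:
            background_rate = 1.0
    rng = np.random.default_rng(seed)
    chrom = "chrS" if annotation is None else str(annotation.regions["chrom"].iloc[0])
    if annotation is not None and annotation.chrom_sizes:
        genome_length = annotation.chrom_sizes[chrom]
    genome = {chrom: _random_seq(rng, genome_length)}

    clusters = cluster_spec.copy()
    if "weight" not in clusters.columns:
        clusters["weight"] = 1.0
    weights = clusters["weight"].to_numpy(dtype=float) if len(clusters) else np.array([])
    if len(weights):
        weights = weights / weights.sum()

    samples = sorted(set(scheme.barcodes.values()))
    sample_barcode = {s: bc for bc, s in scheme.barcodes.items()}
    events: list[tuple[int, str, str, str]] = []  # position, strand, umi, sample
    rows = []
    reads = []
    aln_rows = []
    # crosslink must leave room for the insert: position+1+insert_len <= L on '+'
    lo_plus, hi_plus = 0, genome_length - insert_len - 1
    lo_minus, hi_minus = insert_len, genome_length - 1
    for i in range(n_reads):
        rid = f"read{i+1:07d}"
        sample = samples[int(rng.integers(0, len(samples)))]
        if events and rng.random() < duplication_rate:
            # PCR duplication re-amplifies a molecule within its own library
            pos, strand, umi, sample = events[int(rng.integers(0, len(events)))]
            is_dup = True
        else:
            is_dup = False
            if len(clusters) and rng.random() >= background_rate:
                c = clusters.iloc[int(rng.choice(len(clusters), p=weights))]
                strand = str(c["strand"])
                lo = max(int(c["start"]), lo_plus if strand == "+" else lo_minus)
                hi = min(int(c["end"]) - 1, hi_plus if strand == "+" else hi_minus)
                pos = int(rng.integers(lo, hi + 1))
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                lo, hi = (lo_plus, hi_plus) if strand == "+" else (lo_minus, hi_minus)
                pos = int(rng.integers(lo, hi + 1))
            umi = _random_seq(rng, 3, "AT") + _random_seq(rng, 4)
            events.append((pos, strand, umi, sample))
        if strand == "+":
            start, end = pos + 1, pos + 1 + insert_len
            insert = genome[chrom][start:end]
        else:
            start, end = pos - insert_len, pos
            insert = _revcomp(genome[chrom][start:end])
        seq = umi[:3] + sample_barcode[sample] + umi[3:] + insert
        reads.append((rid, seq))
        aln_rows.append((rid, chrom, start, end, strand, sample, umi))
        rows.append((rid, chrom, pos, strand, umi, sample, is_dup))
    alignments = pd.DataFrame(
        aln_rows, columns=["read_id", "chrom", "start", "end", "strand", "sample_id", "umi"]
    )
    truth_events = pd.DataFrame(
        rows, columns=["read_id", "chrom", "position", "strand", "umi", "sample_id",
                       "is_duplicate"]
    )
    truth_clusters = clusters.assign(chrom=chrom)[["chrom", "start", "end", "strand"]]
    truth = TruthRecord(
        kind="iclip_reads",
        seed=seed,
        params={
            "n_reads": n_reads,
            "background_rate": background_rate,
            "duplication_rate": duplication_rate,
            "genome_length": genome_length,
            "insert_len": insert_len,
        },
        table=truth_events,
    )
    return SimulatedIclip(
        reads=reads,
        alignments=alignments,
        truth_clusters=truth_clusters,
        genome=genome,
        truth=truth,
    )


def default_masks() -> dict[str, Polygon]:
    """A simple cell geometry: square body around the nucleus, protrusion bar."""
    return {
        "body": box(-10.0, -10.0, 10.0, 10.0),
        "protrusion": box(10.0, -2.0, 30.0, 2.0),
        "cell": box(-10.0, -10.0, 30.0, 10.0),
    }


def gen_spot_field(
    n_spots: int = 200,
    displacement: tuple[float, float] = (0.0, 0.0),
    spread: float = 3.0,
    mask_geometry: Mapping[str, Polygon] | None = None,
    nucleus_centroid: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> tuple[SpotField, TruthRecord]:
    """Isotropic Gaussian spot field displaced from the nucleus centroid.

    Spots scatter with standard deviation ``spread`` around
    nucleus_centroid + displacement; intensities are log-normal.  The
    expected polarization index increases with |displacement| / spread.
    """
    if n_spots <= 0:
        raise ValueError("need at least one spot")
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    center = np.asarray(nucleus_centroid, dtype=float) + np.asarray(displacement, dtype=float)
    xy = rng.normal(loc=center, scale=spread, size=(n_spots, 2))
    intensity = rng.lognormal(mean=0.0, sigma=0.3, size=n_spots)
    spots = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "intensity": intensity})
    masks = dict(mask_geometry) if mask_geometry is not None else default_masks()
    field = SpotField(spots=spots, nucleus_centroid=tuple(nucleus_centroid), masks=masks)
    truth = TruthRecord(
        kind="spot_field",
        seed=seed,
        params={"n_spots": n_spots, "displacement_x": displacement[0],
                "displacement_y": displacement[1], "spread": spread},
        table=pd.DataFrame({"displacement_x": [displacement[0]],
                            "displacement_y": [displacement[1]], "spread": [spread]}),
    )
    return field, truth
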