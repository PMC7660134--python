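"""Localization statistics from spot/pixel tables and compartment masks.

Inputs are detected-spot (or thresholded-pixel) tables, not raw images:
segmentation and spot detection are upstream concerns.  The polarization
index quantifies displacement of the RNA signal centroid away from the
nucleus centroid in units of the signal's radius of gyration; mask-based
ratios compare area-normalized signal densities between the protrusion and
cell-body compartments; greedy nearest-neighbor matching quantifies spot
co-localization; per-frame particle counts over mask area give particle
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "SpotField",
    "polarization_index",
    "compartment_signal_ratio",
    "spot_colocalization",
    "particle_density",
    "normalized_stain_intensity",
    "pixels_from_images",
]


@dataclass
class SpotField:
    """Point set with intensities, nucleus centroid and named masks.

    ``spots`` is a DataFrame with columns x, y, intensity (and optionally
    frame); coordinates and mask polygons must share one unit (px or um).
    """

    spots: pd.DataFrame
    nucleus_centroid: tuple[float, float]
    masks: dict[str, Polygon] = field(default_factory=dict)
    frame_id: str | None = None

    def __post_init__(self) -> None:
        missing = {"x", "y", "intensity"} - set(self.spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns: {sorted(missing)}")
        if (self.spots["intensity"].to_numpy(dtype=float) <= 0).any():
            raise ValueError("spot intensities must be positive")

    def in_mask(self, name: str) -> np.ndarray:
        poly = self.masks[name]
        pts = self.spots[["x", "y"]].to_numpy(dtype=float)
        return np.array([poly.covers(Point(x, y)) for x, y in pts])


def polarization_index(field: SpotField, weighted: bool = True) -> float:
    """Polarization index: centroid displacement over radius of gyration.

    PI = sqrt((x_rna - x_cell)^2 + (y_rna - y_cell)^2) / Rg_cell, where
    (x_rna, y_rna) is the (intensity-weighted) spot centroid, (x_cell,
    y_cell) the nucleus centroid, and Rg_cell the root-mean-square distance
    of the spots from the nucleus centroid.  0 = unpolarized; 1 = the whole
    signal displaced as far as it extends.  NaN (flagged undefined) when all
    spots sit on the nucleus centroid.
    """
    xy = field.spots[["x", "y"]].to_numpy(dtype=float)
    if xy.shape[0] == 0:
        raise ValueError("need at least one spot")
    w = field.spots["intensity"].to_numpy(dtype=float) if weighted else np.ones(xy.shape[0])
    w = w / w.sum()
    c = np.asarray(field.nucleus_centroid, dtype=float)
    centroid = (xy * w[:, None]).sum(axis=0)
    rg2 = (w * ((xy - c) ** 2).sum(axis=1)).sum()
    if rg2 == 0:
        return float("nan")
    return float(np.sqrt(((centroid - c) ** 2).sum()) / np.sqrt(rg2))


def compartment_signal_ratio(
    field: SpotField,
    protrusion_mask: str = "protrusion",
    body_mask: str = "body",
    cap: float = 10.0,
) -> tuple[float, str]:
    """Log2 area-normalized signal density ratio, protrusion over body.

    Signal per compartment is the summed intensity of spots inside the mask
    polygon; density is signal over polygon area.  A zero body (or
    protrusion) signal caps the value at +/-``cap`` with a flag instead of
    returning infinity.

    Returns (log2_ratio, flag).
    """
    p_poly = field.masks[protrusion_mask]
    b_poly = field.masks[body_mask]
    if p_poly.area == 0 or b_poly.area == 0:
        raise ValueError("both masks must have positive area")
    w = field.spots["intensity"].to_numpy(dtype=float)
    sig_p = w[field.in_mask(protrusion_mask)].sum()
    sig_b = w[field.in_mask(body_mask)].sum()
    dens_p = sig_p / p_poly.area
    dens_b = sig_b / b_poly.area
    if dens_p == 0 and dens_b == 0:
        return float("nan"), "no_signal"
    if dens_b == 0:
        return cap, "zero_body_signal"
    if dens_p == 0:
        return -cap, "zero_protrusion_signal"
    return float(np.log2(dens_p / dens_b)), "ok"


def spot_colocalization(
    spots_a: pd.DataFrame, spots_b: pd.DataFrame, radius: float
) -> tuple[float, pd.DataFrame]:
    """Percent of A spots co-localized with B within a matching radius.

    Greedy one-to-one matching by increasing pair distance (ties broken by
    A index then B index); each B spot is used at most once.  The result is
    independent of input row order.

    Returns (percent_a_matched, matches).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    a = spots_a[["x", "y"]].to_numpy(dtype=float)
    b = spots_b[["x", "y"]].to_numpy(dtype=float)
    if a.shape[0] == 0:
        raise ValueError("spot set A is empty")
    if b.shape[0] == 0:
        return 0.0, pd.DataFrame(columns=["a_index", "b_index", "distance"])
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    ai, bi = np.nonzero(d <= radius)
    pairs = sorted(zip(d[ai, bi], ai, bi))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for dist, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((int(i), int(j), float(dist)))
    pct = 100.0 * len(used_a) / a.shape[0]
    return pct, pd.DataFrame(matches, columns=["a_index", "b_index", "distance"])


def particle_density(fields: Sequence[SpotField], mask: str = "protrusion") -> float:
    """Mean particles per unit mask area across frames."""
    if len(fields) == 0:
        raise ValueError("need at least one frame")
    dens = []
    for f in fields:
        area = f.masks[mask].area
        if area <= 0:
            raise ValueError("mask area must be positive")
        dens.append(f.in_mask(mask).sum() / area)
    return float(np.mean(dens))


def normalized_stain_intensity(signal_mean: float, reference_mean: float) -> float:
    """Signal mean normalized to a reference stain mean (e.g. OPP to DAPI)."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return float(signal_mean) / float(reference_mean)


def pixels_from_images(
    intensity: np.ndarray, label_image: np.ndarray, threshold: float = 0.0
) -> pd.DataFrame:
    """Convert an intensity image plus label image to a pixel spot table.

    Pixels with intensity above ``threshold`` and a nonzero label become
    rows (x=column, y=row, intensity, label); a convenience shim for
    workflows whose upstream produces label masks rather than spot tables.
    """
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(label_image)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label images must have the same shape")
    yy, xx = np.nonzero((intensity > threshold) & (labels != 0))
    return pd.DataFrame(
        {"x": xx.astype(float), "y": yy.astype(float), "intensity": intensity[yy, xx],
         "label": labels[yy, xx]}
    )
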