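"""Compartment enrichment: paired counts to log2 ratios and category calls.

Turns protrusion/cell-body count pairs into per-sample log2 ratio tables
(CPM scaling, pseudocount, median centering), tests annotation categories
for a localization shift with the rank-based kernel, runs the one-sample t
meta-analysis across cell lines, and classifies knockdown responses with 2D
annotation enrichment (discordant protrusion/body shifts flag candidate
mislocalization; concordant shifts flag expression change).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTable
from .stats import (
    EnrichmentResult,
    annotation_enrichment_2d,
    bh_fdr,
    mwu_category_test,
    one_sample_t_meta,
)

__all__ = [
    "log2_ratio_table",
    "category_shift_test",
    "knockdown_shift_analysis",
    "rbp_meta_volcano",
]


def log2_ratio_table(
    counts: CountTable,
    pseudocount: float = 1.0,
    min_count: int = 10,
    median_center: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample log2(protrusion/body) ratios from a paired count table.

    Counts are library-size scaled to CPM before the ratio; the pseudocount
    is added on the CPM scale; genes whose summed raw counts (P + B) fall
    below ``min_count`` in a sample are set missing for that sample and
    listed in the drop report.  With ``median_center`` each sample's median
    ratio is subtracted (the normalization used downstream of log scaling).

    Returns (ratio_matrix, drop_report).
    """
    design = counts.design
    prot = design[design["compartment"] == "protrusion"].set_index("sample_id")["column"]
    body = design[design["compartment"] == "body"].set_index("sample_id")["column"]
    samples = sorted(set(prot.index) & set(body.index))
    unmatched = set(prot.index) ^ set(body.index)
    if unmatched:
        raise ValueError(f"unmatched protrusion/body columns for samples: {sorted(unmatched)}")
    if not samples:
        raise ValueError("no matched protrusion/body sample pairs")

    ratios = {}
    dropped = []
    for s in samples:
        p_raw = counts.counts[prot[s]].to_numpy(dtype=float)
        b_raw = counts.counts[body[s]].to_numpy(dtype=float)
        p_cpm = p_raw / max(p_raw.sum(), 1.0) * 1e6
        b_cpm = b_raw / max(b_raw.sum(), 1.0) * 1e6
        r = np.log2(p_cpm + pseudocount) - np.log2(b_cpm + pseudocount)
        low = (p_raw + b_raw) < min_count
        r[low] = np.nan
        for gid in counts.feature_ids[low]:
            dropped.append({"feature_id": gid, "sample_id": s, "reason": "below min_count"})
        ratios[s] = r
    table = pd.DataFrame(ratios, index=counts.feature_ids)
    # a gene below threshold in every sample leaves the table entirely
    table = table.dropna(how="all")
    if median_center:
        table = table - table.median(axis=0, skipna=True)
    report = pd.DataFrame(dropped, columns=["feature_id", "sample_id", "reason"])
    return table, report


def category_shift_test(ratios: pd.Series, category: Sequence[str]) -> EnrichmentResult:
    """Rank-based shift test of one category in one ratio column.

    The direction of the shift is the sign of the rank-biserial score.  The
    q field equals p here (single test); when several categories are tested
    together use :func:`protloc.stats.annotation_enrichment_1d`, which
    corrects across categories.
    """
    values = ratios.dropna()
    mask = values.index.isin(list(category))
    U, p, s = mwu_category_test(values.to_numpy(), np.asarray(mask))
    return EnrichmentResult(
        set_name="category", n_members=int(mask.sum()), score_s=s, statistic_U=U, p=p, q=p
    )


def knockdown_shift_analysis(
    ratios_protrusion: pd.Series,
    ratios_body: pd.Series,
    sets: Mapping[str, Sequence[str]],
    fdr: float = 0.02,
    min_members: int = 5,
    full_table: bool = False,
) -> pd.DataFrame:
    """Classify knockdown-response categories by 2D annotation enrichment.

    Both inputs are per-gene log2(NT/KD) vectors, one from the protrusion
    fraction and one from the cell body, on a shared gene universe.
    Significant categories moving in opposite directions in the two
    fractions are labeled mislocalization candidates; concordant ones are
    labeled expression changes.
    """
    shared = ratios_protrusion.index.intersection(ratios_body.index)
    if len(shared) == 0:
        raise ValueError("protrusion and body ratio universes are disjoint")
    x = ratios_protrusion.loc[shared]
    y = ratios_body.loc[shared]
    return annotation_enrichment_2d(
        x, y, sets, fdr=fdr, min_members=min_members, full_table=full_table
    )


def rbp_meta_volcano(
    ratio_panel: pd.DataFrame,
    rbp_set: Sequence[str],
    fdr: float = 0.05,
    min_values: int = 3,
) -> pd.DataFrame:
    """Cross-line meta-analysis volcano with RNA-binding-protein flags.

    One-sample t against 0 per feature across the panel columns (cell
    lines), BH across features; ``is_enriched_rbp`` marks features that are
    in the RBP set, protrusion-enriched (mean > 0) and significant at the
    given FDR.
    """
    meta = one_sample_t_meta(ratio_panel, min_values=min_values)
    meta = meta.rename(columns={"mean": "mean_log2_ratio"})
    in_set = meta.index.isin(list(rbp_set))
    meta["is_rbp"] = in_set
    meta["is_enriched_rbp"] = in_set & (meta["q"] < fdr) & (meta["mean_log2_ratio"] > 0)
    meta.loc[meta["flag"] == "untested", "is_enriched_rbp"] = False
    return meta
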