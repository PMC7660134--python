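"""Pulsed-SILAC translation accounting and nascent-protein localization.

A pulse of medium/heavy isotope-labeled amino acids separates pre-existing
(light) from nascent (medium/heavy) protein.  Whole-cell H/M ratios between
an open-pore (protrusion-forming) and a closed-pore condition measure
translation-rate changes; iBAQ intensities of each label across nuclear,
cytosolic and membrane fractions give the percentage of old versus nascent
protein per compartment.  A spike-in referenced SILAC design quantifies
knockdown-induced proteome shifts.

Input tables are protein-level (one row per protein x replicate x
compartment) with explicit columns::

    protein_id  intensity_L  intensity_M  intensity_H  compartment
    replicate_id  label_scheme

``label_scheme`` is "H_open" or "M_open" and records which heavy channel
carries the open-pore condition in that replicate; the two reciprocal
replicates are harmonized through it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, mwu_category_test

__all__ = [
    "translation_rate_ratios",
    "compartment_fractions",
    "nascent_vs_old_summary",
    "kd_proteome_shift",
]

LABELS = ("L", "M", "H")
COMPARTMENT_ORDER = ("nucleus", "cytosol", "membrane")
SCHEMES = ("H_open", "M_open")


def _check_triplets(triplets: pd.DataFrame) -> None:
    needed = {"protein_id", "intensity_L", "intensity_M", "intensity_H"}
    missing = needed - set(triplets.columns)
    if missing:
        raise ValueError(f"triplet table missing columns: {sorted(missing)}")
    for c in ("intensity_L", "intensity_M", "intensity_H"):
        if (triplets[c].to_numpy(dtype=float) < 0).any():
            raise ValueError("intensities must be non-negative")


def translation_rate_ratios(triplets: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate log2(open/closed) translation-rate ratios.

    Expects whole-cell triplets from two reciprocally labeled replicates.
    The label orientation is harmonized via ``label_scheme``: log2(H/M)
    where H marks the open-pore condition, log2(M/H) otherwise.  Zero
    closed-condition intensities propagate to missing, never to infinity.

    Returns (ratio_matrix, singletons): the matrix holds proteins quantified
    in both replicates (one column per replicate); proteins seen in only one
    go to the side table.
    """
    _check_triplets(triplets)
    if "label_scheme" not in triplets.columns or "replicate_id" not in triplets.columns:
        raise ValueError("triplet table needs replicate_id and label_scheme columns")
    bad = set(triplets["label_scheme"]) - set(SCHEMES)
    if bad:
        raise ValueError(f"unknown label schemes: {sorted(bad)}")

    per_rep = {}
    for rep, grp in triplets.groupby("replicate_id"):
        schemes = grp["label_scheme"].unique()
        if len(schemes) != 1:
            raise ValueError(f"replicate {rep!r} mixes label schemes")
        h = grp["intensity_H"].to_numpy(dtype=float)
        m = grp["intensity_M"].to_numpy(dtype=float)
        open_i, closed_i = (h, m) if schemes[0] == "H_open" else (m, h)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.log2(open_i) - np.log2(closed_i)
        r[(open_i == 0) | (closed_i == 0)] = np.nan
        per_rep[rep] = pd.Series(r, index=grp["protein_id"].to_numpy())
    matrix = pd.DataFrame(per_rep)
    both = matrix.notna().all(axis=1)
    singles = matrix[~both].copy()
    return matrix[both].copy(), singles


def compartment_fractions(triplets: pd.DataFrame) -> pd.DataFrame:
    """Percent of each SILAC label per subcellular compartment and protein.

    For every (protein, label), fraction_c = 100 * iBAQ_c / sum over
    compartments of iBAQ; computed independently per label so old (L) and
    nascent (M, H) pools each distribute to 100%.  Proteins with an all-zero
    label are flagged and get missing fractions for that label.

    Returns a tidy frame: protein_id, label, compartment, percent, flag.
    """
    _check_triplets(triplets)
    if "compartment" not in triplets.columns:
        raise ValueError("triplet table needs a compartment column")
    if triplets["compartment"].nunique() == 0:
        raise ValueError("no compartments present")
    rows = []
    for pid, grp in triplets.groupby("protein_id"):
        for label in LABELS:
            col = f"intensity_{label}"
            vals = grp[col].to_numpy(dtype=float)
            total = vals.sum()
            for comp, v in zip(grp["compartment"], vals):
                if total == 0:
                    rows.append((pid, label, comp, np.nan, "all_zero_label"))
                else:
                    rows.append((pid, label, comp, 100.0 * v / total, "ok"))
    return pd.DataFrame(rows, columns=["protein_id", "label", "compartment", "percent", "flag"])


def nascent_vs_old_summary(
    fractions: pd.DataFrame,
    protein_set: Sequence[str],
    compartments: Sequence[str] = ("nucleus", "cytosol"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Old-versus-nascent compartment distribution for a protein set.

    Summarizes, per label and compartment, the distribution of percentages
    across the proteins (median, quartiles, min-max: box-plot ready), and
    tests whether the nascent pools (M, H) occupy each compartment
    differently from the old pool (L) with a two-tailed homoscedastic
    two-sample t-test.  Both the pooled (unpaired) and the per-protein
    paired variants are reported.

    Returns (summary, tests).
    """
    sel = fractions[
        fractions["protein_id"].isin(list(protein_set))
        & fractions["compartment"].isin(list(compartments))
        & fractions["percent"].notna()
    ]
    if sel["protein_id"].nunique() < 3:
        raise ValueError("need at least 3 proteins with fractions")
    summary_rows = []
    for (label, comp), grp in sel.groupby(["label", "compartment"]):
        v = grp["percent"].to_numpy()
        summary_rows.append(
            {
                "label": label,
                "compartment": comp,
                "n": v.size,
                "median": np.median(v),
                "q1": np.percentile(v, 25),
                "q3": np.percentile(v, 75),
                "min": v.min(),
                "max": v.max(),
            }
        )
    summary = pd.DataFrame(summary_rows)

    test_rows = []
    wide = sel.pivot_table(index="protein_id", columns=["label", "compartment"], values="percent")
    for comp in compartments:
        for nascent in ("M", "H"):
            if ("L", comp) not in wide.columns or (nascent, comp) not in wide.columns:
                continue
            a = wide[("L", comp)].dropna()
            b = wide[(nascent, comp)].dropna()
            t_pooled, p_pooled = sps.ttest_ind(a, b, equal_var=True)
            paired = wide[[("L", comp), (nascent, comp)]].dropna()
            if len(paired) >= 3:
                t_paired, p_paired = sps.ttest_rel(paired[("L", comp)], paired[(nascent, comp)])
            else:
                t_paired, p_paired = np.nan, np.nan
            test_rows.append(
                {
                    "compartment": comp,
                    "comparison": f"L_vs_{nascent}",
                    "t_pooled": float(t_pooled),
                    "p_pooled": float(p_pooled),
                    "t_paired": float(t_paired),
                    "p_paired": float(p_paired),
                }
            )
    return summary, pd.DataFrame(test_rows)


def kd_proteome_shift(
    hl_nt: pd.Series,
    hl_kd: pd.Series,
    sets: Mapping[str, Sequence[str]],
    min_members: int = 5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Knockdown proteome shift from spike-in referenced SILAC ratios.

    Both conditions are referenced to the same heavy spike-in, so
    log2(KD/NT) = log2((H/L)_NT / (H/L)_KD) per protein.  Proteins missing
    a reference ratio in either condition are dropped (reported via the
    returned series' index).  Category shifts are scored with the rank test
    and BH-corrected across categories.

    Returns (log2_kd_over_nt, category_table).
    """
    shared = hl_nt.dropna().index.intersection(hl_kd.dropna().index)
    if len(shared) == 0:
        raise ValueError("no proteins with reference ratios in both conditions")
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_kd = pd.Series(
            np.log2(hl_nt.loc[shared].to_numpy(dtype=float))
            - np.log2(hl_kd.loc[shared].to_numpy(dtype=float)),
            index=shared,
            name="log2_kd_over_nt",
        )
    log2_kd = log2_kd.replace([np.inf, -np.inf], np.nan).dropna()
    rows = []
    for name, feats in sets.items():
        mask = log2_kd.index.isin(list(feats))
        k = int(mask.sum())
        if k < min_members or k == len(log2_kd):
            continue
        U, p, s = mwu_category_test(log2_kd.to_numpy(), np.asarray(mask))
        rows.append((name, k, s, U, p))
    table = pd.DataFrame(rows, columns=["set_name", "n_members", "score_s", "statistic_U", "p"])
    if not table.empty:
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    else:
        table["q"] = []
    return log2_kd, table
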