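"""Shared statistical kernel for annotation enrichment.

The statistics here follow the Perseus-style workflow for category-level
analysis of quantitative omics: a rank-based (adapted Wilcoxon/Mann-Whitney)
test per annotation category with a bounded enrichment score, its
two-dimensional extension for paired contrasts, a one-sample t meta-analysis
across samples, one-sided Fisher/hypergeometric over-representation, and
Benjamini-Hochberg multiple-testing control.

The Mann-Whitney test is implemented from first principles because the
category score ``s = 2*U/(n1*n2) - 1`` (rank-biserial correlation) and the
exact tie-aware permutation null are the analysis-defining primitives; scipy
is used only for distribution functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "Enrichment2DResult",
    "bh_fdr",
    "mwu_category_test",
    "annotation_enrichment_1d",
    "annotation_enrichment_2d",
    "one_sample_t_meta",
    "fisher_over_representation",
]

# n1*n2 at or below this uses the exact tie-aware permutation null
EXACT_SWITCH = 200
DEFAULT_MIN_MEMBERS = 5


@dataclass
class EnrichmentResult:
    """Category-level rank-test result.

    ``score_s`` is the rank-biserial enrichment score in (-1, 1): +1 means
    every member ranks above every non-member, 0 means no rank separation.
    """

    set_name: str
    n_members: int
    score_s: float
    statistic_U: float
    p: float
    q: float = float("nan")

    def _row(self) -> dict:
        return {
            "set_name": self.set_name,
            "n_members": self.n_members,
            "score_s": self.score_s,
            "statistic_U": self.statistic_U,
            "p": self.p,
            "q": self.q,
        }


@dataclass
class Enrichment2DResult:
    """Two-dimensional category enrichment across a pair of contrasts."""

    set_name: str
    n_members: int
    score_x: float
    score_y: float
    q_x: float
    q_y: float
    joint_q: float
    quadrant: str
    label: str


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving: returns q in the input order.  Raises on p outside
    [0, 1] or non-finite input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(ranks: np.ndarray, member_mask: np.ndarray) -> float:
    """Exact two-sided permutation p-value for the member rank-sum.

    Dynamic programming over the multiset of (doubled, hence integer)
    midranks counts, for every subset size k and rank-sum s, the number of
    k-subsets achieving s.  Ties are handled exactly because midranks are
    permuted as observed.
    """
    n = ranks.size
    n1 = int(member_mask.sum())
    r2 = np.round(ranks * 2).astype(np.int64)  # midranks*2 are integers
    total = int(r2.sum())
    # counts[k, s] = number of size-k subsets with doubled-rank-sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in r2:
        # iterate k downwards so each item is used at most once
        for k in range(min(n1, 1_000_000), 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    dist = counts[n1]
    n_total = dist.sum()
    obs = int(r2[member_mask].sum())
    n2 = n - n1
    # two-sided via distance of U (equivalently rank-sum) from its mean
    mean_s = n1 * (total / n)
    dev = abs(obs - mean_s)
    sums = np.arange(total + 1, dtype=float)
    p = dist[np.abs(sums - mean_s) >= dev - 1e-9].sum() / n_total
    return float(min(1.0, p))


def mwu_category_test(values, members) -> tuple[float, float, float]:
    """Adapted Wilcoxon/Mann-Whitney test of a category against its complement.

    Parameters
    ----------
    values
        1-D array of finite scores over the analysis universe (entries that
        are NaN are dropped together with their membership flags).
    members
        Boolean mask over ``values`` or an index array selecting category
        members.

    Returns
    -------
    (U, p, score_s)
        ``U`` counts member-over-complement wins (ties half); ``score_s`` is
        the rank-biserial score ``2*U/(n1*n2) - 1``; ``p`` is two-sided, from
        the exact tie-aware permutation null when ``n1*n2 <= 200`` and from
        the tie-corrected normal approximation with continuity correction
        otherwise.
    """
    v = np.asarray(values, dtype=float)
    mask = np.zeros(v.size, dtype=bool)
    members = np.asarray(members)
    if members.dtype == bool:
        if members.size != v.size:
            raise ValueError("boolean member mask must match values length")
        mask = members.copy()
    else:
        mask[members] = True
    keep = np.isfinite(v)
    v, mask = v[keep], mask[keep]
    n = v.size
    n1 = int(mask.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("category must be a non-empty proper subset of the universe")
    ranks = _midranks(v)
    r1 = ranks[mask].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    score_s = 2.0 * U / (n1 * n2) - 1.0

    # degenerate: every value identical -> no rank information
    if np.all(v == v[0]):
        return float(U), 1.0, 0.0

    if n1 * n2 <= EXACT_SWITCH:
        p = _exact_rank_sum_p(ranks, mask)
    else:
        mu = n1 * n2 / 2.0
        # tie correction on the variance
        _, tie_counts = np.unique(v, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return float(U), 1.0, 0.0
        z = (abs(U - mu) - 0.5) / np.sqrt(sigma2)
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return float(U), float(p), float(score_s)


def _resolve_sets(
    sets: Mapping[str, Sequence[str]],
    universe: pd.Index,
    min_members: int,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Intersect annotation sets with the universe, dropping small ones."""
    masks: dict[str, np.ndarray] = {}
    skipped = []
    for name, feats in sets.items():
        if len(feats) == 0:
            raise ValueError(f"annotation set {name!r} is empty")
        mask = universe.isin(list(feats))
        k = int(mask.sum())
        if k < min_members:
            skipped.append({"set_name": name, "n_in_universe": k, "reason": "below min_members"})
        elif k == len(universe):
            skipped.append({"set_name": name, "n_in_universe": k, "reason": "equals universe"})
        else:
            masks[name] = np.asarray(mask)
    skipped_df = pd.DataFrame(skipped, columns=["set_name", "n_in_universe", "reason"])
    return masks, skipped_df


def annotation_enrichment_1d(
    values: pd.Series,
    sets: Mapping[str, Sequence[str]],
    fdr: float = 0.02,
    min_members: int = DEFAULT_MIN_MEMBERS,
    full_table: bool = False,
):
    """1D annotation enrichment: one rank test per category, BH across sets.

    ``values`` is a feature-indexed Series of scores (e.g. mean log2 ratios).
    Returns a DataFrame of categories with q < ``fdr`` sorted by q (or the
    full unfiltered table when ``full_table``), plus a skipped-sets report.
    """
    values = values.dropna()
    if values.empty:
        raise ValueError("empty universe")
    masks, skipped = _resolve_sets(sets, values.index, min_members)
    rows = []
    for name, mask in masks.items():
        U, p, s = mwu_category_test(values.to_numpy(), mask)
        rows.append(EnrichmentResult(name, int(mask.sum()), s, U, p)._row())
    table = pd.DataFrame(rows, columns=["set_name", "n_members", "score_s", "statistic_U", "p", "q"])
    if not table.empty:
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    if not full_table:
        table = table[table["q"] < fdr].reset_index(drop=True)
    return table, skipped


_QUADRANTS = {
    (1, 1): ("correlated_up", "expression change"),
    (-1, -1): ("correlated_down", "expression change"),
    (1, -1): ("anti_correlated_x_up", "mislocalization candidate"),
    (-1, 1): ("anti_correlated_y_up", "mislocalization candidate"),
}


def annotation_enrichment_2d(
    values_x: pd.Series,
    values_y: pd.Series,
    sets: Mapping[str, Sequence[str]],
    fdr: float = 0.02,
    min_members: int = DEFAULT_MIN_MEMBERS,
    full_table: bool = False,
) -> pd.DataFrame:
    """2D annotation enrichment over a shared universe.

    Each category is scored independently in both dimensions; it is called
    significant when either dimension passes BH at ``fdr`` (joint_q =
    min(q_x, q_y)).  The quadrant of the two score signs separates
    concordant ("expression change") from discordant ("mislocalization
    candidate") categories.
    """
    shared = values_x.dropna().index.intersection(values_y.dropna().index)
    if len(shared) == 0:
        raise ValueError("x and y universes are disjoint")
    if not values_x.index.equals(values_y.index):
        raise ValueError("x and y must be defined on the same universe")
    vx = values_x.loc[shared]
    vy = values_y.loc[shared]
    masks, _ = _resolve_sets(sets, shared, min_members)
    rows = []
    for name, mask in masks.items():
        _, px, sx = mwu_category_test(vx.to_numpy(), mask)
        _, py, sy = mwu_category_test(vy.to_numpy(), mask)
        rows.append((name, int(mask.sum()), sx, sy, px, py))
    table = pd.DataFrame(rows, columns=["set_name", "n_members", "score_x", "score_y", "p_x", "p_y"])
    if table.empty:
        table["q_x"] = table["q_y"] = table["joint_q"] = []
        table["quadrant"] = table["label"] = []
        return table
    table["q_x"] = bh_fdr(table["p_x"].to_numpy())
    table["q_y"] = bh_fdr(table["p_y"].to_numpy())
    table["joint_q"] = np.minimum(table["q_x"], table["q_y"])
    quad, label = [], []
    for sx, sy in zip(table["score_x"], table["score_y"]):
        key = (1 if sx >= 0 else -1, 1 if sy >= 0 else -1)
        qd, lb = _QUADRANTS[key]
        quad.append(qd)
        label.append(lb)
    table["quadrant"] = quad
    table["label"] = label
    table = table.sort_values(["joint_q", "set_name"]).reset_index(drop=True)
    if not full_table:
        table = table[table["joint_q"] < fdr].reset_index(drop=True)
    return table


def one_sample_t_meta(ratio_matrix: pd.DataFrame, min_values: int = 3) -> pd.DataFrame:
    """Per-feature one-sample t-test against 0 across samples, BH-corrected.

    Features with fewer than ``min_values`` non-missing values are reported
    untested (NaN statistics, flag "untested"); zero-variance rows get p=0
    when the mean is nonzero, p=1 otherwise, flagged "degenerate".  BH runs
    across all tested features.
    """
    X = ratio_matrix.to_numpy(dtype=float)
    n_obs = np.isfinite(X).sum(axis=1)
    means = np.full(X.shape[0], np.nan)
    ts = np.full(X.shape[0], np.nan)
    ps = np.full(X.shape[0], np.nan)
    flags = np.full(X.shape[0], "ok", dtype=object)
    for i, row in enumerate(X):
        vals = row[np.isfinite(row)]
        if vals.size < min_values:
            flags[i] = "untested"
            continue
        m = vals.mean()
        sd = vals.std(ddof=1)
        means[i] = m
        if sd == 0:
            flags[i] = "degenerate"
            ps[i] = 0.0 if m != 0 else 1.0
            ts[i] = np.inf * np.sign(m) if m != 0 else 0.0
            continue
        t = m / (sd / np.sqrt(vals.size))
        ts[i] = t
        ps[i] = 2.0 * sps.t.sf(abs(t), df=vals.size - 1)
    out = pd.DataFrame(
        {"mean": means, "t": ts, "p": ps, "q": np.nan, "n": n_obs, "flag": flags},
        index=ratio_matrix.index,
    )
    tested = out["flag"] != "untested"
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def fisher_over_representation(
    target: Sequence[str],
    universe: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    fdr: float = 0.02,
    full_table: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of categories in a target.

    For each category with K members in the universe, the p-value is the
    upper tail P(X >= k) of Hypergeometric(N, K, n) where n = |target| and
    k = |target ∩ category|.  Categories disjoint from the universe are
    excluded.  BH runs across tested categories.
    """
    uni = pd.Index(pd.unique(pd.Series(list(universe))))
    tgt = set(target)
    if not tgt:
        raise ValueError("target set is empty")
    if not tgt.issubset(set(uni)):
        raise ValueError("target must be a subset of the universe")
    N, n = len(uni), len(tgt)
    rows = []
    for name, feats in sets.items():
        members = uni.isin(list(feats))
        K = int(members.sum())
        if K == 0:
            continue
        k = len(tgt.intersection(uni[members]))
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, min(1.0, p)))
    table = pd.DataFrame(rows, columns=["set_name", "n_in_universe", "n_in_target", "p"])
    if table.empty:
        table["q"] = []
        return table
    table["q"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["q", "p", "set_name"]).reset_index(drop=True)
    if not full_table:
        table = table[table["q"] < fdr].reset_index(drop=True)
    return table
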