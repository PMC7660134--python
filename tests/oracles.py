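"""Independent brute-force oracles used to verify the statistical kernel
and the density clustering.  Everything here is literal enumeration or
hand-rolled arithmetic, deliberately sharing no code path with protloc.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def bh_stepup_literal(pvals):
    """Textbook BH: sort, multiply by m/rank, enforce monotone, unsort."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = min(1.0, val)
        prev = val
    return q


def mwu_enumeration(values, member_indices):
    """Exact two-sided MWU p by full enumeration over member subsets.

    Enumerates all C(n, n1) assignments of the member labels to the
    observed midranks; two-sided tail by distance of the member rank-sum
    from its null mean.
    """
    ranks = rankdata(values)
    n = len(values)
    n1 = len(member_indices)
    obs = float(ranks[list(member_indices)].sum())
    mean = n1 * (n + 1) / 2.0
    dev = abs(obs - mean)
    hits = total = 0
    for combo in combinations(range(n), n1):
        s = float(ranks[list(combo)].sum())
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for Hypergeometric(N, K, n) by direct summation."""
    total = 0.0
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / denom
    return total


def _density(positions, values, a, b):
    return sum(values[a : b + 1]) / (positions[b] + 1 - positions[a])


def _cohesion(positions, values, a, b):
    cs = []
    for k in range(a, b + 1):
        cs.append(_density(positions, values, a, k))  # prefix ending at k
        cs.append(_density(positions, values, k, b))  # suffix starting at k
    return min(cs)


def cluster_family_bruteforce(positions, values, literal_parents=False):
    """All density clusters of one strand track, by direct enumeration.

    An interval of consecutive sites is a cluster when its cohesion (the
    minimum density over all its prefixes and suffixes, itself included)
    strictly exceeds the cohesion of every strictly containing interval.
    Returns tuples (start, end, sum, max_density, min_density) in
    half-open genomic coordinates.

    ``literal_parents`` enumerates every superset explicitly (O(n^4),
    tiny n only); otherwise the containing maximum is accumulated by a
    simple dynamic program over interval endpoints.
    """
    n = len(positions)
    coh = {}
    for a in range(n):
        for b in range(a, n):
            coh[(a, b)] = _cohesion(positions, values, a, b)
    if literal_parents:
        parent = {}
        for a in range(n):
            for b in range(a, n):
                sup = [
                    coh[(x, y)]
                    for x in range(a + 1)
                    for y in range(b, n)
                    if (x, y) != (a, b)
                ]
                parent[(a, b)] = max(sup) if sup else -math.inf
    else:
        parent = {}
        for a in range(n):
            for b in range(n - 1, a - 1, -1):
                best = -math.inf
                if a > 0:
                    best = max(best, coh[(a - 1, b)], parent[(a - 1, b)])
                if b < n - 1:
                    best = max(best, coh[(a, b + 1)], parent[(a, b + 1)])
                parent[(a, b)] = best
    out = []
    for (a, b), c in sorted(coh.items()):
        if c > parent[(a, b)]:
            out.append(
                (
                    positions[a],
                    positions[b] + 1,
                    float(sum(values[a : b + 1])),
                    c,
                    max(parent[(a, b)], 0.0),
                )
            )
    return out


def paraclu_bruteforce(positions, values, min_sum=10.0, max_len=200, min_fold=2.0):
    """Reported clusters (filtered + overlap-resolved) from the brute force.

    Overlap resolution mirrors the documented rule — keep the higher
    stability fold, ties broken by shorter then leftmost — implemented
    here independently with plain lists.
    """
    fam = cluster_family_bruteforce(positions, values)
    candidates = []
    for start, end, total, max_d, min_d in fam:
        fold = math.inf if min_d == 0 else max_d / min_d
        if total >= min_sum and (end - start) <= max_len and fold >= min_fold:
            candidates.append((start, end, total, max_d, min_d, fold))
    candidates.sort(key=lambda c: (-c[5], c[1] - c[0], c[0], c[1]))
    kept = []
    for c in candidates:
        if all(not (c[0] < k[1] and k[0] < c[1]) for k in kept):
            kept.append(c)
    kept.sort()
    return kept
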