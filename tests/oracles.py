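"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exhaustive enumeration
for the hypergeometric tail, lattice enumeration for closed itemsets, a
from-scratch agglomerator for Ward linkage, the textbook step-up for BH,
and a double loop over pairs for the confusion counts.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np


def hypergeom_tail_enum(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws. Only for tiny N."""
    population = list(range(N))
    successes = set(range(K))
    hits = total = 0
    for draw in combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def closed_itemsets_enum(
    transactions: dict[str, frozenset[str]], min_support: int
) -> dict[frozenset[str], frozenset[str]]:
    """All closed frequent itemsets by powerset enumeration.

    ``transactions`` maps a transaction id to its item set.  Returns
    {itemset: supporting transaction ids} for every closed itemset with
    support >= min_support.
    """
    items = sorted(set(chain.from_iterable(transactions.values())))
    by_itemset: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            itemset = frozenset(combo)
            tids = frozenset(
                t for t, its in transactions.items() if itemset <= its
            )
            if len(tids) >= min_support:
                by_itemset[itemset] = tids
    closed = {}
    for itemset, tids in by_itemset.items():
        # closed iff no strict superset has the same support set
        if not any(
            other > itemset and otids == tids
            for other, otids in by_itemset.items()
        ):
            closed[itemset] = tids
    return closed


def ward_merges_enum(
    dist: np.ndarray,
) -> list[tuple[frozenset[int], frozenset[int], float]]:
    """Ward.D agglomeration re-done from scratch with dict bookkeeping.

    Clusters are keyed by creation index (leaves 0..n-1, then n, n+1, ...);
    ties at equal distance go to the smallest (i, j) pair.  Returns the
    merge sequence as (members_a, members_b, height).
    """
    n = dist.shape[0]
    members: dict[int, frozenset[int]] = {i: frozenset({i}) for i in range(n)}
    d: dict[frozenset[int], float] = {
        frozenset((i, j)): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    merges = []
    while len(members) > 1:
        ids = sorted(members)
        best = min(
            ((d[frozenset((i, j))], i, j)
             for a, i in enumerate(ids) for j in ids[a + 1:]),
            key=lambda t: t,
        )
        h, i, j = best
        merged = members[i] | members[j]
        ni, nj = len(members[i]), len(members[j])
        for k in ids:
            if k in (i, j):
                continue
            nk = len(members[k])
            d[frozenset((next_id, k))] = (
                (ni + nk) * d[frozenset((i, k))]
                + (nj + nk) * d[frozenset((j, k))]
                - nk * h
            ) / (ni + nj + nk)
        merges.append((members[i], members[j], h))
        del members[i], members[j]
        members[next_id] = merged
        next_id += 1
    return merges


def bh_adjust_enum(pvalues: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def pair_confusion_enum(found, reference_groups, genes):
    """TP/FP/FN/TN by an explicit double loop over all gene pairs."""
    genes = sorted(set(genes))
    found = [set(g) for g in found]
    ref = [set(g) for g in reference_groups]
    tp = fp = fn = tn = 0
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            in_found = any(a in g and b in g for g in found)
            in_ref = any(a in g and b in g for g in ref)
            if in_found and in_ref:
                tp += 1
            elif in_found:
                fp += 1
            elif in_ref:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
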